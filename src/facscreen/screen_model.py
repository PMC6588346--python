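"""Domain types and table I/O for FACS-bin CRISPRi reporter screens.

A pooled CRISPRi reporter screen sorts a library-transduced cell population
into a high- and a low-fluorescence FACS bin in each treatment arm and
sequences the sgRNA-encoded protospacers of each bin.  The objects here hold
the three tables every downstream module consumes:

* :class:`LibraryDesign` — the sgRNA library (protospacer, target gene,
  negative-control membership),
* :class:`BinCounts` — integer read counts per sgRNA for one (arm, bin)
  sample,
* a growth-phenotype table (plain ``pandas.Series``) mapping gene -> gamma,
  the fitness phenotype from an independent growth screen.

All tables are read and written as UTF-8 tab-separated files.  ``#``-prefixed
lines before the header carry ``key=value`` metadata (used by
:class:`BinCounts` for its arm/bin labels); they keep the files greppable and
diff-able.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("facscreen")

#: Sentinel target label marking non-targeting negative-control sgRNAs.
NEG_CTRL = "NEG_CTRL"

#: Treatment arms: ER stress alone vs ER stress plus the ATF6 inhibitor.
ARMS = ("tm", "tm_ceapin")

#: FACS bins: top and bottom tails of the reporter-fluorescence distribution.
BINS = ("high", "low")

#: Protospacers of the individually retested sgRNAs (sequencing fixture).
#: NegCtrl and ATF6 are 21-mers; the rest are 20-mers.
TABLE1_PROTOSPACERS = {
    "NegCtrl": "GCGCCAAACGTGCCCTGACGG",
    "ATF6": "GTGGGATCTGAGAATGTACCA",
    "ABCD3-1": "GGTACCAGCGAGCCGGCGAG",
    "ABCD3-2": "GACTGCCGGTACCAGCGAGC",
    "PEX19-1": "GGCCGAAGCGGACAGGGAAT",
    "PEX19-2": "GGAGGAAGGCTGTAGTGTCG",
    "ACBD4": "GCCGGCCCTGCTGGACCCCG",
    "ACBD5": "GGGAGCCGCTCTCCCACCCT",
    "VAPA": "GCACCGAACCGGTGACACAG",
    "VAPB": "GCGGGGGTCCTCTACCGGGT",
}

_VALID_BASES = frozenset("ACGT")


class ScreenModelError(ValueError):
    """Raised on malformed library, count or growth tables."""


def is_control_label(target: str) -> bool:
    """True for any spelling of the negative-control sentinel.

    Accepts ``NEG_CTRL``, ``NegCtrl``, ``negctrl`` etc. so that library
    tables from different sources parse without renaming.
    """
    return str(target).upper().replace("_", "").replace("-", "") == "NEGCTRL"


@dataclass
class LibraryDesign:
    """An sgRNA library: one row per sgRNA.

    Parameters
    ----------
    df
        Columns ``sgrna_id``, ``protospacer``, ``target``, ``tss``.
        ``target`` is a gene label or the negative-control sentinel.
    k
        Expected number of sgRNAs per targeted gene (compact genome-scale
        CRISPRi libraries use 5).  Deviations are warnings by default,
        errors with ``strict=True``.
    """

    df: pd.DataFrame
    k: int = 5
    strict: bool = False

    def __post_init__(self) -> None:
        required = ["sgrna_id", "protospacer", "target"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ScreenModelError(f"library table missing columns: {missing}")
        df = self.df.copy()
        if "tss" not in df.columns:
            df["tss"] = ""
        df["tss"] = df["tss"].fillna("")
        if len(df) == 0:
            raise ScreenModelError("no sgRNAs in library")
        dup = df["sgrna_id"][df["sgrna_id"].duplicated()]
        if len(dup):
            raise ScreenModelError(f"duplicate sgrna_id: {sorted(set(dup))}")
        for sg, proto in zip(df["sgrna_id"], df["protospacer"]):
            if not isinstance(proto, str) or not proto or set(proto) - _VALID_BASES:
                raise ScreenModelError(f"non-ACGT protospacer for {sg}: {proto!r}")
            if not 19 <= len(proto) <= 21:
                raise ScreenModelError(
                    f"protospacer for {sg} has length {len(proto)}, expected 19-21"
                )
        df["is_control"] = df["target"].map(is_control_label)
        self.df = df.reset_index(drop=True)
        bad_k = {
            gene: n
            for gene, n in self.df.loc[~self.df.is_control, "target"]
            .value_counts()
            .items()
            if n != self.k
        }
        if bad_k:
            msg = f"genes with sgRNA count != k={self.k}: {bad_k}"
            if self.strict:
                raise ScreenModelError(msg)
            logger.warning(msg)

    @property
    def sgrna_ids(self) -> pd.Index:
        return pd.Index(self.df["sgrna_id"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.df.loc[self.df.is_control, "sgrna_id"])

    @property
    def genes(self) -> list[str]:
        """Targeted genes, in order of first appearance."""
        targets = self.df.loc[~self.df.is_control, "target"]
        return list(dict.fromkeys(targets))

    @property
    def n_sgrnas(self) -> int:
        return len(self.df)

    def gene_sgrnas(self, gene: str) -> list[str]:
        return list(self.df.loc[self.df.target == gene, "sgrna_id"])

    def protospacer_length(self) -> int:
        """The common protospacer length; error if heterogeneous."""
        lengths = {len(p) for p in self.df["protospacer"]}
        if len(lengths) != 1:
            raise ScreenModelError(
                f"heterogeneous protospacer lengths {sorted(lengths)}"
            )
        return lengths.pop()


@dataclass
class BinCounts:
    """Read counts per sgRNA for one (arm, bin) sequencing sample."""

    arm: str
    bin: str
    counts: pd.Series
    unmapped: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ScreenModelError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if self.bin not in BINS:
            raise ScreenModelError(f"unknown bin {self.bin!r}; expected one of {BINS}")
        counts = pd.Series(self.counts)
        if (counts < 0).any():
            bad = counts[counts < 0]
            raise ScreenModelError(f"negative counts: {bad.to_dict()}")
        if counts.index.duplicated().any():
            raise ScreenModelError("duplicate sgrna_id in counts")
        if self.unmapped < 0:
            raise ScreenModelError("negative unmapped count")
        self.counts = counts.astype(np.int64)
        self.counts.index.name = "sgrna_id"

    @property
    def total_reads(self) -> int:
        """Mapped + unmapped reads; the mapped/unmapped split always sums to this."""
        return int(self.counts.sum()) + int(self.unmapped)

    @property
    def mapped_reads(self) -> int:
        return int(self.counts.sum())

    def check_ids(self, design: LibraryDesign, policy: str = "error") -> "BinCounts":
        """Validate count ids against a library.

        policy='error' raises on ids absent from the library; policy='drop'
        removes them (adding their reads to ``unmapped``) with a warning.
        """
        known = set(design.sgrna_ids)
        unknown = [i for i in self.counts.index if i not in known]
        if not unknown:
            return self
        if policy == "error":
            raise ScreenModelError(f"counts contain unknown sgrna_id: {unknown}")
        if policy == "drop":
            dropped = int(self.counts.loc[unknown].sum())
            logger.warning(
                "dropping %d unknown sgRNAs (%d reads) from (%s, %s)",
                len(unknown), dropped, self.arm, self.bin,
            )
            kept = self.counts.drop(index=unknown)
            return BinCounts(self.arm, self.bin, kept, self.unmapped + dropped)
        raise ValueError(f"unknown policy {policy!r}")


# ---------------------------------------------------------------------------
# TSV I/O


def _read_metadata(path: Path) -> tuple[dict, int]:
    meta: dict[str, str] = {}
    n_meta = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta, n_meta


def read_library(path: str | Path, k: int = 5, strict: bool = False) -> LibraryDesign:
    """Read a library design TSV (columns sgrna_id, protospacer, target, tss)."""
    path = Path(path)
    _, n_meta = _read_metadata(path)
    df = pd.read_csv(path, sep="\t", skiprows=n_meta, dtype=str)
    if len(df) == 0:
        raise ScreenModelError(f"no sgRNAs in {path}")
    return LibraryDesign(df, k=k, strict=strict)


def write_library(design: LibraryDesign, path: str | Path) -> None:
    cols = ["sgrna_id", "protospacer", "target", "tss"]
    design.df[cols].to_csv(path, sep="\t", index=False)


def write_library_fasta(design: LibraryDesign, path: str | Path) -> None:
    """Export protospacers as FASTA, sgrna_id as header."""
    with open(path, "w", encoding="utf-8") as fh:
        for sg, proto in zip(design.df.sgrna_id, design.df.protospacer):
            fh.write(f">{sg}\n{proto}\n")


def read_counts(
    path: str | Path,
    design: LibraryDesign | None = None,
    arm: str | None = None,
    bin: str | None = None,
    unknown_policy: str = "error",
) -> BinCounts:
    """Read a per-sample count TSV.

    Arm and bin come from ``# arm=...`` / ``# bin=...`` metadata lines unless
    overridden by the keyword arguments.
    """
    path = Path(path)
    meta, n_meta = _read_metadata(path)
    df = pd.read_csv(path, sep="\t", skiprows=n_meta)
    if "sgrna_id" not in df.columns or "count" not in df.columns:
        raise ScreenModelError(f"{path}: expected columns sgrna_id, count")
    arm = arm or meta.get("arm")
    bin_ = bin or meta.get("bin")
    if arm is None or bin_ is None:
        raise ScreenModelError(f"{path}: arm/bin not given in metadata or arguments")
    counts = pd.Series(df["count"].to_numpy(), index=df["sgrna_id"])
    bc = BinCounts(arm, bin_, counts, unmapped=int(meta.get("unmapped", 0)))
    if design is not None:
        bc = bc.check_ids(design, policy=unknown_policy)
    return bc


def write_counts(bc: BinCounts, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# arm={bc.arm}\n# bin={bc.bin}\n# unmapped={bc.unmapped}\n")
        fh.write(f"# total_reads={bc.total_reads}\n")
        bc.counts.rename("count").to_csv(fh, sep="\t")


def read_growth(path: str | Path) -> pd.Series:
    """Read a growth-phenotype table (columns gene, gamma) as a Series."""
    _, n_meta = _read_metadata(Path(path))
    df = pd.read_csv(path, sep="\t", skiprows=n_meta)
    if "gene" not in df.columns or "gamma" not in df.columns:
        raise ScreenModelError(f"{path}: expected columns gene, gamma")
    gamma = pd.Series(df["gamma"].to_numpy(float), index=df["gene"], name="gamma")
    if not np.isfinite(gamma).all():
        raise ScreenModelError("non-finite growth phenotype")
    gamma.index.name = "gene"
    return gamma


def write_growth(gamma: pd.Series, path: str | Path) -> None:
    out = gamma.rename("gamma").copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def write_gene_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats.to_csv(path, sep="\t", index=False)


def read_gene_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("hit", "control"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
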