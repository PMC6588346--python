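"""Exact-match protospacer counting from FASTQ reads.

Each read carries the sgRNA-identifying protospacer at a fixed offset inside
constant flanking sequence.  A read is assigned to the unique library sgRNA
whose protospacer equals ``read[offset:offset + length]``; anything else —
mismatches, truncated reads — is unmapped.  Exact matching in fixed
orientation is the reproducible baseline for amplicon screens; mismatch
tolerance is deliberately not implemented.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .screen_model import BinCounts, LibraryDesign


class QuantifyError(ValueError):
    pass


@dataclass(frozen=True)
class MappingStats:
    total: int
    mapped: int
    unmapped: int

    @property
    def mapping_rate(self) -> float:
        """Fraction of reads assigned; 0 for an empty input."""
        return self.mapped / self.total if self.total else 0.0


def _protospacer_index(design: LibraryDesign, length: int) -> dict[str, str]:
    lib_length = design.protospacer_length()
    if lib_length != length:
        raise QuantifyError(
            f"library protospacers are {lib_length} nt but length={length}"
        )
    index: dict[str, str] = {}
    for sg, proto in zip(design.df.sgrna_id, design.df.protospacer):
        if proto in index:
            raise QuantifyError(
                f"duplicate protospacer {proto} ({index[proto]} vs {sg}): "
                "assignment would be ambiguous"
            )
        index[proto] = sg
    return index


def iter_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a plain or gzipped FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq


def count_protospacers(
    reads: str | Path | Iterable[str],
    design: LibraryDesign,
    offset: int,
    length: int,
    arm: str = "tm",
    bin: str = "high",
) -> tuple[BinCounts, MappingStats]:
    """Count exact protospacer matches in a read stream.

    Parameters
    ----------
    reads
        A FASTQ path (``.gz`` accepted) or any iterable of read sequences.
    offset, length
        Protospacer coordinates within each read; ``length`` must equal the
        library's uniform protospacer length.
    arm, bin
        Sample labels stamped onto the returned :class:`BinCounts`.
    """
    if offset < 0 or length <= 0:
        raise QuantifyError("offset must be >= 0 and length > 0")
    index = _protospacer_index(design, length)
    if isinstance(reads, (str, Path)):
        reads = iter_fastq_sequences(reads)

    counts = dict.fromkeys(design.sgrna_ids, 0)
    total = unmapped = 0
    end = offset + length
    for seq in reads:
        total += 1
        sg = index.get(seq[offset:end]) if len(seq) >= end else None
        if sg is None:
            unmapped += 1      # mismatch or read too short: never an error
        else:
            counts[sg] += 1
    bc = BinCounts(arm, bin, pd.Series(counts), unmapped=unmapped)
    return bc, MappingStats(total=total, mapped=total - unmapped,
                            unmapped=unmapped)
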