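"""TMT IP-MS quantification: bait normalization and analog-selectivity ranking.

In a tandem-mass-tag immunoprecipitation experiment every channel (one
treatment x replicate) reports raw reporter-ion intensities per protein.
Pulldown efficiency varies by channel, so intensities are first divided by
the same channel's intensity of the immunoprecipitated bait; the bait row
becomes all ones and channel-wide scale factors cancel.  Treatment ratios
(e.g. drug/vehicle) are means of normalized intensities over a treatment's
channels, and candidate interactors are ranked by the selectivity contrast
between the active compound and an inactive analog.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

TREATMENTS = ("dmso", "tg_ceapin_a5", "tg_ceapin_a7")


class IPMSError(ValueError):
    pass


@dataclass
class TMTTable:
    """Protein x channel intensity matrix with channel treatment labels.

    Parameters
    ----------
    intensities
        Nonnegative reals; index = protein ids, columns = channel names.
    channels
        Frame with columns ``channel, treatment, replicate``; every
        intensity column must appear.
    bait_id
        The immunoprecipitated protein; must be present with intensity > 0
        in every channel.
    """

    intensities: pd.DataFrame
    channels: pd.DataFrame
    bait_id: str

    def __post_init__(self) -> None:
        for col in ("channel", "treatment"):
            if col not in self.channels.columns:
                raise IPMSError(f"channel metadata missing column {col!r}")
        known = set(self.channels["channel"])
        missing = [c for c in self.intensities.columns if c not in known]
        if missing:
            raise IPMSError(f"channels without metadata: {missing}")
        if (self.intensities.to_numpy(float) < 0).any():
            raise IPMSError("negative intensity")
        if self.bait_id not in self.intensities.index:
            raise IPMSError(f"bait {self.bait_id!r} not in table")
        bait = self.intensities.loc[self.bait_id]
        if (bait <= 0).any():
            bad = list(bait.index[bait <= 0])
            raise IPMSError(f"bait intensity <= 0 in channels {bad}")

    def treatment_channels(self, treatment: str) -> list[str]:
        sel = self.channels.loc[self.channels.treatment == treatment,
                                "channel"]
        return [c for c in self.intensities.columns if c in set(sel)]


def read_tmt(
    intensities_path: str | Path,
    channels_path: str | Path,
    bait_id: str,
) -> TMTTable:
    """Read an intensity TSV (protein, one column per channel) plus channel
    metadata TSV (channel, treatment, replicate)."""
    inten = pd.read_csv(intensities_path, sep="\t", index_col=0)
    chan = pd.read_csv(channels_path, sep="\t", dtype=str)
    return TMTTable(inten.astype(float), chan, bait_id)


def normalize_to_bait(table: TMTTable) -> TMTTable:
    """Divide every intensity by the same channel's bait intensity.

    Idempotent: the bait row of a normalized table is all ones.
    """
    bait = table.intensities.loc[table.bait_id]
    normalized = table.intensities.div(bait, axis="columns")
    return TMTTable(normalized, table.channels, table.bait_id)


def treatment_ratios(
    table: TMTTable, numerator: str, denominator: str
) -> pd.Series:
    """Per-protein ratio of mean normalized intensity between treatments.

    Replicate channels of each treatment are combined by arithmetic mean.
    Proteins undetected (mean 0) under the denominator get ``+inf``; they
    carry a flag downstream rather than being dropped.  Expects a
    bait-normalized table (applies :func:`normalize_to_bait` defensively,
    which is a no-op on already-normalized input).
    """
    table = normalize_to_bait(table)
    num_ch = table.treatment_channels(numerator)
    den_ch = table.treatment_channels(denominator)
    if not num_ch:
        raise IPMSError(f"no channels labeled {numerator!r}")
    if not den_ch:
        raise IPMSError(f"no channels labeled {denominator!r}")
    num = table.intensities[num_ch].mean(axis=1)
    den = table.intensities[den_ch].mean(axis=1)
    with np.errstate(divide="ignore"):
        ratio = num / den
    ratio[(num == 0) & (den == 0)] = np.nan
    return ratio.rename(f"{numerator}/{denominator}")


def rank_candidates(
    ratios_active: pd.Series,
    ratios_inactive: pd.Series,
    bait_id: str | None = None,
) -> pd.DataFrame:
    """Rank proteins by the active/inactive selectivity contrast.

    ``contrast = ratio_active / ratio_inactive``; descending order, ties
    kept in input order (stable sort).  Rows with a non-finite ratio or
    contrast are flagged (``undetected=True``) and ranked after all finite
    contrasts.  The bait, enriched by construction, is excluded.
    """
    missing = set(ratios_active.index).symmetric_difference(
        ratios_inactive.index)
    if missing:
        raise IPMSError(
            f"proteins absent from one ratio table: {sorted(missing)[:5]}"
        )
    df = pd.DataFrame({
        "ratio_active": ratios_active,
        "ratio_inactive": ratios_inactive.reindex(ratios_active.index),
    })
    if bait_id is not None:
        df = df.drop(index=bait_id, errors="ignore")
    with np.errstate(divide="ignore", invalid="ignore"):
        df["contrast"] = df["ratio_active"] / df["ratio_inactive"]
    finite = np.isfinite(df["contrast"].to_numpy(float))
    df["undetected"] = ~finite
    sort_key = np.where(finite, df["contrast"].to_numpy(float), -np.inf)
    order = np.argsort(-sort_key, kind="stable")
    out = df.iloc[order].reset_index().rename(columns={"index": "protein"})
    out.index.name = "rank"
    return out.reset_index().assign(rank=lambda d: d["rank"] + 1)
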