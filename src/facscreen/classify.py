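"""Two-arm comparison: Ceapin-dependence categories and the volcano export.

A gene's category is a pure function of its hit status in the two treatment
arms (stress alone, ``tm``; stress plus inhibitor, ``tm_ceapin``):

=============  ==============  ====================
hit in tm      hit in tm+drug  category
=============  ==============  ====================
True           True            ceapin_independent
False          True            ceapin_hit
True           False           tm_only_hit
False          False           none
=============  ==============  ====================

Dual-arm hits are drug-independent because their phenotype does not depend
on the inhibitor; genes hit only with the drug present are the drug's
candidate targets (their knockdown restores reporter induction the drug
otherwise blocks).  Growth-defect genes (gamma <= gamma*, default -0.19,
i.e. a growth defect of at least that magnitude) are annotated, not
recategorized, matching how screen volcanoes color them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CATEGORY_ORDER = ("ceapin_hit", "ceapin_independent", "tm_only_hit", "none")


class ClassifyError(ValueError):
    pass


def categorize(hit_tm: bool, hit_tm_ceapin: bool) -> str:
    """Category of one gene from its two arm-level hit flags."""
    if hit_tm and hit_tm_ceapin:
        return "ceapin_independent"
    if hit_tm_ceapin:
        return "ceapin_hit"
    if hit_tm:
        return "tm_only_hit"
    return "none"


def classify_genes(
    stats_tm: pd.DataFrame,
    stats_tm_ceapin: pd.DataFrame,
    growth: pd.Series | None = None,
    gamma_star: float = -0.19,
) -> pd.DataFrame:
    """Join the two arms' gene statistics into per-gene classifications.

    Both frames must cover the same gene universe (including control
    pseudogenes, which ride through with ``negative_control=True``).
    Returns columns ``gene, category, negative_control, growth_flagged,
    hit_tm, hit_tm_ceapin, rho_tm, rho_tm_ceapin, gamma``.
    """
    a = stats_tm.set_index("gene")
    b = stats_tm_ceapin.set_index("gene")
    if set(a.index) != set(b.index):
        only_a = sorted(set(a.index) - set(b.index))
        only_b = sorted(set(b.index) - set(a.index))
        raise ClassifyError(
            f"gene universes differ between arms: only_tm={only_a[:5]}, "
            f"only_tm_ceapin={only_b[:5]}"
        )
    b = b.reindex(a.index)
    out = pd.DataFrame({
        "gene": a.index,
        "hit_tm": a["hit"].to_numpy(bool),
        "hit_tm_ceapin": b["hit"].to_numpy(bool),
        "rho_tm": a["rho"].to_numpy(float),
        "rho_tm_ceapin": b["rho"].to_numpy(float),
        "negative_control": a["control"].to_numpy(bool)
        if "control" in a.columns else False,
    }).reset_index(drop=True)
    out["category"] = [
        categorize(h1, h2)
        for h1, h2 in zip(out["hit_tm"], out["hit_tm_ceapin"])
    ]
    if growth is not None:
        gamma = growth.reindex(out["gene"]).to_numpy(float)
        out["gamma"] = gamma
        out["growth_flagged"] = np.where(
            np.isnan(gamma), False, gamma <= gamma_star)
    else:
        out["gamma"] = np.nan
        out["growth_flagged"] = False
    return out[["gene", "category", "negative_control", "growth_flagged",
                "hit_tm", "hit_tm_ceapin", "rho_tm", "rho_tm_ceapin",
                "gamma"]]


def volcano_table(
    stats_tm: pd.DataFrame,
    stats_tm_ceapin: pd.DataFrame,
    classes: pd.DataFrame,
) -> pd.DataFrame:
    """One row per gene with both arms' rho, p, score and the category.

    This is the data behind a two-arm volcano / diagonal comparison plot;
    plotting itself is left to the caller.
    """
    a = stats_tm.set_index("gene")
    b = stats_tm_ceapin.set_index("gene").reindex(a.index)
    c = classes.set_index("gene").reindex(a.index)
    return pd.DataFrame({
        "gene": a.index,
        "rho_tm": a["rho"], "p_tm": a["p"], "score_tm": a["score"],
        "rho_tm_ceapin": b["rho"], "p_tm_ceapin": b["p"],
        "score_tm_ceapin": b["score"],
        "category": c["category"],
        "negative_control": c["negative_control"],
        "growth_flagged": c["growth_flagged"],
    }).reset_index(drop=True)
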