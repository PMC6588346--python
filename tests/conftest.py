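import numpy as np
import pandas as pd
import pytest

import facscreen as fs
from facscreen.screen_model import NEG_CTRL, TABLE1_PROTOSPACERS


@pytest.fixture
def small_params():
    """Desk-scale simulation: fast but large enough to gate and sequence."""
    return fs.SimulationParams(
        n_genes=12, n_control_sgrnas=15, coverage=120,
        reads_per_bin=60_000, seed=7,
    )


@pytest.fixture
def small_design(small_params):
    return fs.make_default_library(small_params)


@pytest.fixture
def toy_design():
    """Hand-sized library: 2 genes x 5 sgRNAs + 4 controls, fixed sequences."""
    rng = np.random.default_rng(123)
    bases = np.array(list("ACGT"))
    protos = ["".join(bases[rng.integers(0, 4, 20)]) for _ in range(14)]
    rows = []
    for g in range(2):
        for j in range(5):
            rows.append((f"g{g}_sg{j}", protos[g * 5 + j], f"g{g}", f"g{g}"))
    for c in range(4):
        rows.append((f"ctrl{c}", protos[10 + c], NEG_CTRL, ""))
    return fs.LibraryDesign(
        pd.DataFrame(rows, columns=["sgrna_id", "protospacer", "target", "tss"])
    )


@pytest.fixture
def table1_library_file(tmp_path):
    """Library TSV holding the ten individually validated protospacers."""
    path = tmp_path / "table1.tsv"
    lines = ["sgrna_id\tprotospacer\ttarget\ttss"]
    for name, proto in TABLE1_PROTOSPACERS.items():
        gene = name.split("-")[0]
        lines.append(f"{name}\t{proto}\t{gene}\t{gene}")
    path.write_text("\n".join(lines) + "\n")
    return path


def make_counts(design, hi, lo, arm="tm"):
    """BinCounts pair from two count vectors aligned to the library order."""
    ids = design.sgrna_ids
    return (
        fs.BinCounts(arm, "high", pd.Series(hi, index=ids)),
        fs.BinCounts(arm, "low", pd.Series(lo, index=ids)),
    )


@pytest.fixture
def tmt_fixture():
    """Six-channel TMT IP: bait, one active-analog-selective prey, background.

    ABCD3-like prey is ~8x enriched over vehicle only under the active
    compound; background proteins ride along at constant normalized level.
    """
    channels = pd.DataFrame({
        "channel": [f"ch{i}" for i in range(6)],
        "treatment": ["dmso", "dmso", "tg_ceapin_a5", "tg_ceapin_a5",
                      "tg_ceapin_a7", "tg_ceapin_a7"],
        "replicate": [1, 2, 1, 2, 1, 2],
    })
    # bait varies by channel (pulldown efficiency); preys scale with it
    bait = np.array([100., 80., 120., 90., 110., 95.])
    rows = {
        "ATF6": bait,
        "ABCD3": bait * np.array([0.05, 0.05, 0.05, 0.05, 0.4, 0.4]),
        "SQSTM1": bait * np.array([0.2, 0.2, 0.3, 0.3, 0.3, 0.3]),
        "HSPA8": bait * 0.5,
        "KRT1": bait * 1.5,
    }
    intensities = pd.DataFrame(rows, index=channels.channel).T
    return fs.TMTTable(intensities, channels, "ATF6")
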