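import numpy as np
import pandas as pd
import pytest

from ppbscreen import (ChannelLayout, ChannelRole, PSMTable, default_layout)


@pytest.fixture(scope="session")
def layout() -> ChannelLayout:
    """The reference 11-plex: 4 cell lines x 2 replicates + 3 blanks."""
    return default_layout()


@pytest.fixture(scope="session")
def small_layout() -> ChannelLayout:
    """Minimal valid design: one line per species in duplicate + 2 blanks."""
    roles = {
        "c1": ChannelRole("sample", cell_line="H1", replicate=1),
        "c2": ChannelRole("sample", cell_line="H1", replicate=2),
        "c3": ChannelRole("sample", cell_line="M1", replicate=1),
        "c4": ChannelRole("sample", cell_line="M1", replicate=2),
        "c5": ChannelRole("blank", blank_index=1),
        "c6": ChannelRole("blank", blank_index=2),
    }
    return ChannelLayout(("c1", "c2", "c3", "c4", "c5", "c6"), roles,
                         {"H1": "human", "M1": "mouse"}, "c5")


def make_psm_table(intensities, channels, specificity=None, proteins=None,
                  peptides=None) -> PSMTable:
    """Build a PSMTable from a 2-D intensity array and minimal metadata."""
    inten = np.asarray(intensities, dtype=float)
    n = inten.shape[0]
    data = pd.DataFrame({
        "psm_id": [f"PSM{i:04d}" for i in range(n)],
        "peptide": list(peptides) if peptides is not None
                   else [f"pep{i}" for i in range(n)],
        "protein": list(proteins) if proteins is not None
                   else [f"prot{i}" for i in range(n)],
        "canonical_protein": list(proteins) if proteins is not None
                             else [f"prot{i}" for i in range(n)],
        "species_specificity": list(specificity) if specificity is not None
                               else ["shared"] * n,
    })
    data[list(channels)] = inten
    return PSMTable(data, tuple(channels))
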