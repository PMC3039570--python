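import numpy as np
import pandas as pd
import pytest

from centralprot import synthetic as syn
from centralprot.goflux import GOSlim


@pytest.fixture(scope="session")
def small_config():
    return syn.SyntheticConfig(seed=1, n_proteins=120, n_nodes=150, n_bp_terms=12)


@pytest.fixture(scope="session")
def proteome(small_config):
    return syn.generate_proteome(small_config)


@pytest.fixture(scope="session")
def psm_data(small_config, proteome):
    return syn.generate_psm_tables(proteome, small_config)


@pytest.fixture(scope="session")
def sequences(proteome):
    seqs = dict(proteome)
    seqs.update(syn.decoy_sequences(proteome))
    return seqs


@pytest.fixture(scope="session")
def annotated_graph(small_config):
    graph, truth = syn.generate_annotated_interactome(small_config)
    return graph, truth


@pytest.fixture(scope="session")
def slim():
    # root -> {metabolism, transport}; metabolism -> {glycolysis, tca}
    return GOSlim(
        parents={
            "root": set(),
            "metabolism": {"root"},
            "transport": {"root"},
            "glycolysis": {"metabolism"},
            "tca": {"metabolism"},
        }
    )


def make_psm_rows(rows, cell_line="CL1", engine="A"):
    """Build a PSM table from (spectrum_id, peptide, score, protein_ids) tuples."""
    out = []
    for r in rows:
        sid, pep, score, prot = r[:4]
        is_decoy = r[4] if len(r) > 4 else False
        pvalue = r[5] if len(r) > 5 else np.nan
        out.append(
            {
                "spectrum_id": sid,
                "cell_line": cell_line,
                "engine": engine,
                "peptide": pep,
                "score": score,
                "pvalue": pvalue,
                "protein_ids": prot,
                "is_decoy": is_decoy,
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "spectrum_id",
            "cell_line",
            "engine",
            "peptide",
            "score",
            "pvalue",
            "protein_ids",
            "is_decoy",
        ],
    )
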