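import numpy as np
import pytest

import flymap as fm

CELL_TYPES = ["T1", "T2", "T3"]
CONDITIONS = ["ctrl", "880"]


@pytest.fixture(scope="session")
def catalog20():
    """20 synthetic metabolic pathways over a 1,000-gene universe."""
    return fm.generate_pathway_catalog(
        n_categories=4,
        n_pathways=20,
        genes_per_pathway=(10, 25),
        gene_universe_size=1000,
        overlap_fraction=0.0,
        seed=1,
    )


def make_design(
    seed,
    n_per_group=150,
    pathway_programs=(),
    lr_plantings=(),
    correlation_blocks=(),
    markers_per_type=40,
    n_genes=1000,
    occupancy=None,
):
    """Population design used across the suite: 3 cell types x 2 conditions."""
    if occupancy is None:
        n_nuclei = {(t, c): n_per_group for t in CELL_TYPES for c in CONDITIONS}
    else:
        n_nuclei = occupancy
    return fm.PopulationDesign(
        cell_types=CELL_TYPES,
        conditions=CONDITIONS,
        n_nuclei=n_nuclei,
        n_genes=n_genes,
        markers_per_type=markers_per_type,
        pathway_programs=list(pathway_programs),
        lr_plantings=list(lr_plantings),
        correlation_blocks=list(correlation_blocks),
        seed=seed,
    )


@pytest.fixture(scope="session")
def population(catalog20):
    """A normalized population with one planted pathway program and one
    correlation block; shared read-only across tests."""
    design = make_design(
        seed=11,
        pathway_programs=[fm.PathwayProgram("T1", "880", "pw005", 1.0)],
        correlation_blocks=[
            fm.CorrelationBlock(("pw010", "pw011", "pw012", "pw013", "pw014"), 0.6)
        ],
    )
    adata, truth = fm.generate_cell_population(design, catalog20)
    return fm.normalize_log1p(adata), truth


@pytest.fixture(scope="session")
def null_population(catalog20):
    """No planted effects at all: conditions are exchangeable."""
    design = make_design(seed=12, markers_per_type=0)
    adata, truth = fm.generate_cell_population(design, catalog20)
    return fm.normalize_log1p(adata), truth
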