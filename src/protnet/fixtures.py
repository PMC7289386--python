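"""Packaged reference fixtures (component census, annotations, memberships).

Small plain-text tables shipped with the package for consistency checks and
demos: the component size census and edge census of the reference breast
cancer cohort analysis, the nine annotated large components with their main
functions, the 13-member extracellular-matrix component, and a miniature
annotation table covering the proteins those fixtures mention.

The component-13 membership list is *partly synthetic*: publicly printed
sources name 11 of its 13 proteins, so two stand-in members (SYNC13A,
SYNC13B) complete it to the documented node count.  They carry no annotation
and therefore never affect enrichment overlaps.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotation import AnnotationTable
from .components import Component

#: background size used with the packaged annotation fixture (order of the
#: annotated human genome, the convention for hypergeometric enrichment)
FIXTURE_BACKGROUND = 20_000


def _data_path(name: str):
    return resources.files("protnet.data").joinpath(name)


def load_table1_distribution() -> dict[int, int]:
    """Component size -> count census of the reference cohort network."""
    df = pd.read_csv(_data_path("table1_size_distribution.tsv"), sep="\t")
    return dict(zip(df["n_nodes"].astype(int), df["n_components"].astype(int)))


def load_edge_census() -> dict[str, int]:
    """Guided (directed) and undetermined (undirected) edge counts."""
    df = pd.read_csv(_data_path("edge_census.tsv"), sep="\t")
    return dict(zip(df["edge_type"], df["count"].astype(int)))


def load_table2_components() -> pd.DataFrame:
    """The nine annotated components: id, node count, curated main function."""
    return pd.read_csv(_data_path("table2_components.tsv"), sep="\t")


def load_component13() -> Component:
    """The 13-protein extracellular-matrix component (2 synthetic stand-ins)."""
    df = pd.read_csv(_data_path("component13_synthetic.tsv"), sep="\t")
    return Component(
        id="Component 13",
        members=tuple(sorted(df["protein_id"])),
        major_function="Extracellular matrix",
        function_source="override",
    )


def load_annotation_fixture() -> AnnotationTable:
    """Miniature offline annotation table for the packaged fixtures."""
    df = pd.read_csv(_data_path("annotations_fixture.tsv"), sep="\t", dtype=str)
    return AnnotationTable(df, background=FIXTURE_BACKGROUND)
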