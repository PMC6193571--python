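"""Delimited-text readers and writers for every table the package uses.

All formats are plain CSV.  Pedigrees use ``id,dam,sire,generation,sex,
is_breeder`` with 0 (or an empty field) for unknown parents.  Square
matrices are written dense with the ids as header row and first column.
Networks are two-column edge lists.  Epialleles get a sidecar
``<stem>.classes.csv`` file with the per-island class labels.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from pedvar.containers import LabeledMatrix
from pedvar.nongenetic import EpialleleTable


def write_pedigree(ped: pd.DataFrame, path) -> None:
    ped.to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path)
    for col in ("dam", "sire"):
        ped[col] = ped[col].fillna(0).astype(int)
    ped["is_breeder"] = ped["is_breeder"].astype(bool)
    if "extra_pair" in ped.columns:
        ped["extra_pair"] = ped["extra_pair"].astype(bool)
    return ped


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_matrix(mat: LabeledMatrix, path) -> None:
    mat.to_frame().to_csv(path, index_label="id")


def read_matrix(path, kind: str = "") -> LabeledMatrix:
    df = pd.read_csv(path, index_col=0)
    df.columns = [int(c) for c in df.columns]
    return LabeledMatrix.from_frame(df, kind=kind)


def write_edgelist(net: nx.Graph, path) -> None:
    pd.DataFrame(sorted(net.edges), columns=["i", "j"]).to_csv(path, index=False)


def read_edgelist(path, nodes=None) -> nx.Graph:
    edges = pd.read_csv(path)
    G = nx.Graph()
    if nodes is not None:
        G.add_nodes_from(int(n) for n in nodes)
    G.add_edges_from(zip(edges["i"].astype(int), edges["j"].astype(int)))
    return G


def write_epialleles(epi: EpialleleTable, path) -> None:
    path = Path(path)
    epi.counts.to_csv(path, index_label="id")
    sidecar = path.with_suffix(".classes.csv")
    pd.DataFrame(
        {"island": epi.counts.columns, "class": epi.island_class}
    ).to_csv(sidecar, index=False)


def read_epialleles(path) -> EpialleleTable:
    path = Path(path)
    counts = pd.read_csv(path, index_col="id")
    sidecar = pd.read_csv(path.with_suffix(".classes.csv"))
    return EpialleleTable(counts=counts, island_class=sidecar["class"].to_numpy())
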