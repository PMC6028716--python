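"""Node universe and file I/O shared by the pipeline.

The node set of every network is an atlas table: one row per region of
interest (ROI), with a contiguous 0-based ``node_id``, a unique name, a
hemisphere and a coarse anatomical class.  The packaged default atlas has
87 regions: the 68 Desikan-Killiany cortical parcels plus bilateral
subcortical, cerebellar and brainstem structures, with gray and white
matter merged per structure.  Names are advisory; only the count and the
region-class groupings carry analytical weight.

All matrices handled here are full square delimited-text tables with a
header row of node names, stored in atlas order.
"""

from __future__ import annotations

import importlib.resources
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

HEMISPHERES = {"left", "right", "midline"}
REGION_CLASSES = {
    "frontal", "temporal", "parietal", "occipital", "cingulate", "insula",
    "basal_ganglia", "diencephalon", "cerebellum", "brainstem", "other",
}

__all__ = [
    "AtlasNodeTable", "WeightedNetwork", "load_atlas", "default_atlas",
    "make_atlas", "load_cohort", "read_matrix", "write_matrix",
    "read_network", "write_network",
]


class AtlasValidationError(ValueError):
    """Raised when an atlas table violates uniqueness/contiguity rules."""


@dataclass(frozen=True)
class AtlasNodeTable:
    """Validated node table; rows are in node_id order."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = ["node_id", "name", "hemisphere", "region_class"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise AtlasValidationError(f"atlas missing columns: {missing}")
        if t["name"].duplicated().any():
            dups = sorted(t.loc[t["name"].duplicated(), "name"])
            raise AtlasValidationError(f"duplicate node names: {dups}")
        ids = np.asarray(t["node_id"], dtype=int)
        if not np.array_equal(np.sort(ids), np.arange(len(t))):
            raise AtlasValidationError(
                "node_ids must be contiguous integers starting at 0"
            )
        bad_h = set(t["hemisphere"]) - HEMISPHERES
        if bad_h:
            raise AtlasValidationError(f"unknown hemisphere values: {bad_h}")
        bad_c = set(t["region_class"]) - REGION_CLASSES
        if bad_c:
            raise AtlasValidationError(f"unknown region_class values: {bad_c}")
        object.__setattr__(
            self, "table", t.sort_values("node_id").reset_index(drop=True)
        )

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    def index_of(self, names: Iterable[str]) -> np.ndarray:
        """Positions of the given node names in atlas order."""
        lookup = {n: i for i, n in enumerate(self.names)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown node name: {exc.args[0]}") from None


@dataclass
class WeightedNetwork:
    """Symmetric connectivity-probability network over atlas nodes.

    ``weights`` is n x n, symmetric, zero-diagonal, nonnegative; entry
    (i, j) is the non-directional connection probability between ROIs i
    and j.
    """

    weights: np.ndarray
    atlas: AtlasNodeTable
    subject_id: str = ""

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"weights must be square, got shape {W.shape}")
        if W.shape[0] != self.atlas.n_nodes:
            raise ValueError(
                f"weights shape {W.shape} does not match atlas size "
                f"{self.atlas.n_nodes}"
            )
        if not np.allclose(W, W.T, rtol=0.0, atol=0.0):
            raise ValueError("weights must be exactly symmetric")
        if np.any(np.diag(W) != 0.0):
            raise ValueError("diagonal must be zero")
        if np.any(W < 0.0):
            raise ValueError("weights must be nonnegative")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Nonzero undirected edges as (i, j, weight) with i < j."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        w = self.weights[iu, ju]
        nz = w > 0.0
        return list(zip(iu[nz].tolist(), ju[nz].tolist(), w[nz].tolist()))


def load_atlas(path: str | Path) -> AtlasNodeTable:
    """Read an atlas CSV (node_id,name,hemisphere,region_class)."""
    return AtlasNodeTable(pd.read_csv(path))


def default_atlas() -> AtlasNodeTable:
    """The packaged 87-region atlas."""
    ref = importlib.resources.files("strucnet.data") / "atlas_dk87.csv"
    with importlib.resources.as_file(ref) as p:
        return load_atlas(p)


def make_atlas(n_nodes: int) -> AtlasNodeTable:
    """A generic n-node atlas for simulations at non-default sizes.

    Nodes alternate hemispheres (node 2k left, 2k+1 right; a trailing odd
    node is midline) so block-structured templates remain meaningful.
    """
    if n_nodes == 87:
        return default_atlas()
    rows = []
    for i in range(n_nodes):
        if n_nodes % 2 == 1 and i == n_nodes - 1:
            hemi = "midline"
        else:
            hemi = "left" if i % 2 == 0 else "right"
        rows.append((i, f"node{i:03d}", hemi, "other"))
    return AtlasNodeTable(
        pd.DataFrame(rows, columns=["node_id", "name", "hemisphere", "region_class"])
    )


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV (subject_id, group, clinical scores).

    Blank score cells are allowed; PANSS/GAF are expected only for the
    patient group.
    """
    df = pd.read_csv(path)
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_ids in cohort table")
    bad = set(df["group"]) - {"patient", "control"}
    if bad:
        raise ValueError(f"unknown group labels: {bad}")
    return df


def read_matrix(
    path: str | Path, atlas: AtlasNodeTable, *, require_symmetric: bool = False
) -> np.ndarray:
    """Read a square delimited matrix and align it to atlas node order.

    The file must be TSV or CSV with a header row of node names and one
    row per node (first column = node name).  A permuted header is
    accepted and re-ordered; unknown or missing names raise.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    names = list(df.columns)
    if sorted(names) != sorted(atlas.names):
        unknown = set(names) - set(atlas.names)
        missing = set(atlas.names) - set(names)
        raise ValueError(
            f"matrix header does not match atlas: unknown={sorted(unknown)!r} "
            f"missing={sorted(missing)!r}"
        )
    if list(df.index) != names:
        raise ValueError("matrix row labels must equal its column header")
    try:
        M = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from None
    order = atlas.index_of(names)
    # scatter file order back into atlas order
    out = np.empty_like(M)
    out[np.ix_(order, order)] = M
    if require_symmetric and not np.allclose(out, out.T, rtol=0.0, atol=0.0):
        raise ValueError(f"matrix in {path} is not symmetric")
    return out


def write_matrix(M: np.ndarray, atlas: AtlasNodeTable, path: str | Path) -> None:
    """Write a matrix as TSV/CSV with node-name header, full precision."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.DataFrame(M, index=atlas.names, columns=atlas.names)
    df.to_csv(path, sep=sep, float_format="%.17g")


def write_network(
    net: WeightedNetwork, path: str | Path, format: str = "tsv"
) -> None:
    """Write a network as a TSV matrix or as GraphML.

    The TSV round-trips through :func:`read_network` at full floating
    precision.  GraphML emits one ``<node>`` per atlas node and one
    ``<edge>`` per nonzero undirected weight.
    """
    if format == "tsv":
        write_matrix(net.weights, net.atlas, path)
    elif format == "graphml":
        _write_graphml(net, path)
    else:
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'graphml'")


def read_network(
    path: str | Path, atlas: AtlasNodeTable, subject_id: str = ""
) -> WeightedNetwork:
    W = read_matrix(path, atlas, require_symmetric=True)
    return WeightedNetwork(W, atlas, subject_id)


_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def _write_graphml(net: WeightedNetwork, path: str | Path) -> None:
    ET.register_namespace("", _GRAPHML_NS)
    root = ET.Element(f"{{{_GRAPHML_NS}}}graphml")
    key = ET.SubElement(root, f"{{{_GRAPHML_NS}}}key")
    key.set("id", "weight")
    key.set("for", "edge")
    key.set("attr.name", "weight")
    key.set("attr.type", "double")
    graph = ET.SubElement(root, f"{{{_GRAPHML_NS}}}graph")
    graph.set("id", net.subject_id or "network")
    graph.set("edgedefault", "undirected")
    for name in net.atlas.names:
        node = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}node")
        node.set("id", name)
    names = net.atlas.names
    for i, j, w in net.edge_list():
        edge = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}edge")
        edge.set("source", names[i])
        edge.set("target", names[j])
        data = ET.SubElement(edge, f"{{{_GRAPHML_NS}}}data")
        data.set("key", "weight")
        data.text = repr(w)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
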