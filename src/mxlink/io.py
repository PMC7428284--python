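"""Readers and writers for multiplex edge-list formats.

Two on-disk layouts are supported:

* **combined** — one file, one record per edge: ``layer nodeA nodeB [weight]``,
  whitespace separated, ``#`` comments.  Header comments of the form
  ``# layer: NAME`` declare layers, so empty layers survive a round trip.
  This matches widely circulated multiplex dataset releases.
* **per-layer** — a directory with a ``manifest.yaml`` mapping layer names to
  edge-list filenames (``u v [w]`` records) and an optional node-universe
  file (one label per line).

All layers are coerced to undirected, unweighted simple graphs: records are
symmetrized and deduplicated, self-loops dropped, and any nonzero weight
counts as an edge (zero-weight records are ignored).
"""

from __future__ import annotations

import os
from typing import Sequence

import yaml

from .core import EdgeSet, MultiplexNetwork, _label_sort_key
from .errors import ConfigurationError, ParseError

__all__ = ["read_multiplex", "write_multiplex"]

_LAYER_HEADER = "# layer:"


def read_multiplex(path: str, format: str = "combined") -> MultiplexNetwork:
    """Read a multiplex network from disk.

    Parameters
    ----------
    path : str
        Combined edge-list file, or a per-layer directory.
    format : {"combined", "per-layer"}

    Raises
    ------
    ParseError
        Malformed record (reported with its line number) or no edges at all.
    ConfigurationError
        Unknown format, or a per-layer manifest referencing a missing file.
    """
    if format == "combined":
        return _read_combined(path)
    if format == "per-layer":
        return _read_per_layer(path)
    raise ConfigurationError(f"unknown format {format!r}; use 'combined' or 'per-layer'")


def _parse_edge_tokens(tokens, path, lineno, with_layer):
    want = 3 if with_layer else 2
    if len(tokens) not in (want, want + 1):
        raise ParseError(
            f"expected {want} or {want + 1} fields, got {len(tokens)}: {' '.join(tokens)!r}",
            path=path,
            line=lineno,
        )
    weight = 1.0
    if len(tokens) == want + 1:
        try:
            weight = float(tokens[-1])
        except ValueError:
            raise ParseError(
                f"non-numeric weight {tokens[-1]!r}", path=path, line=lineno
            ) from None
    if with_layer:
        return tokens[0], tokens[1], tokens[2], weight
    return None, tokens[0], tokens[1], weight


def _read_combined(path: str) -> MultiplexNetwork:
    layer_edges: dict[str, list] = {}
    seen_nodes: set = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith(_LAYER_HEADER):
                name = line[len(_LAYER_HEADER):].strip()
                layer_edges.setdefault(name, [])
                continue
            if not line or line.startswith("#"):
                continue
            layer, u, v, w = _parse_edge_tokens(line.split(), path, lineno, True)
            layer_edges.setdefault(layer, [])
            seen_nodes.update((u, v))
            if w != 0 and u != v:
                layer_edges[layer].append((u, v))
    if not any(layer_edges.values()):
        raise ParseError("no edges", path=path)
    universe = sorted(seen_nodes, key=_label_sort_key)
    return MultiplexNetwork.from_edge_lists(layer_edges, node_universe=universe)


def _read_per_layer(path: str) -> MultiplexNetwork:
    manifest_path = os.path.join(path, "manifest.yaml")
    if not os.path.exists(manifest_path):
        raise ConfigurationError(f"per-layer directory {path!r} has no manifest.yaml")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh) or {}
    layer_files = manifest.get("layers")
    if not isinstance(layer_files, dict) or not layer_files:
        raise ConfigurationError(f"{manifest_path}: manifest must map 'layers' to {{name: file}}")

    universe = None
    nodes_file = manifest.get("nodes")
    if nodes_file:
        nodes_path = os.path.join(path, nodes_file)
        if not os.path.exists(nodes_path):
            raise ConfigurationError(f"node-universe file {nodes_path!r} not found")
        with open(nodes_path) as fh:
            universe = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]

    layer_edges: dict[str, list] = {}
    seen_nodes: set = set()
    for name, fname in layer_files.items():
        fpath = os.path.join(path, fname)
        if not os.path.exists(fpath):
            raise ConfigurationError(
                f"manifest layer {name!r} references missing file {fpath!r}"
            )
        pairs = []
        with open(fpath) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                _, u, v, w = _parse_edge_tokens(line.split(), fpath, lineno, False)
                seen_nodes.update((u, v))
                if w != 0 and u != v:
                    pairs.append((u, v))
        layer_edges[str(name)] = pairs
    if not any(layer_edges.values()):
        raise ParseError("no edges", path=path)
    if universe is None:
        universe = sorted(seen_nodes, key=_label_sort_key)
    return MultiplexNetwork.from_edge_lists(layer_edges, node_universe=universe)


def write_multiplex(net: MultiplexNetwork, path: str) -> None:
    """Write the combined format: header layer declarations, then one line
    per edge (``layer u v``) with endpoints ordered by node-label order and
    layers in declaration order."""
    try:
        with open(path, "w") as fh:
            fh.write("# multiplex edge list: layer nodeA nodeB\n")
            for name in net.layer_names:
                fh.write(f"{_LAYER_HEADER} {name}\n")
            for name in net.layer_names:
                for i, j in sorted(net.layer(name).edges):
                    fh.write(f"{name} {net.node_labels[i]} {net.node_labels[j]}\n")
    except OSError as exc:
        raise OSError(f"cannot write multiplex file {path!r}: {exc}") from exc


def write_node_universe(labels: Sequence, path: str) -> None:
    """One node label per line (companion file for the per-layer layout)."""
    with open(path, "w") as fh:
        for lab in labels:
            fh.write(f"{lab}\n")
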