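"""Phylogenetic trees as BON vertex/edge graphs.

A tree is encoded as a graph with two sets: ``vertices`` (each with a
unique ``id``, an optional taxon ``name`` and, when branch lengths exist,
a ``branch_length`` on the *child* vertex of the branch) and ``edges``
(each with mandatory ``id``, ``source`` and ``target`` plus optional
free-form metadata such as a rate estimate and its confidence interval).
This mirrors the structure NeXML and GraphML use and, unlike Newick,
leaves no semantic ambiguity about what a number or label belongs to.

In a BON payload each object is one tree: the mandatory attribute
``tree`` holds the graph (the obvious candidate for whole-value
compression) and any further keys are tree-level metadata that stays
readable while the tree itself is compressed.

Beyond strictly bifurcating or multifurcating trees the representation
also admits ancestral recombination graphs: ``arg`` mode relaxes
validation from tree-ness to a connected DAG, where recombination nodes
have two incoming edges (each of which can carry, say, the breakpoint
location in the alignment).  Only the representation is provided; no ARG
inference happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import dendropy

from .core import BonBlock, BonObject, CompressionSpec, decode_object, encode_block
from .errors import FormatError, GraphError

PHYLO_DEFAULT_SPEC = CompressionSpec({"tree"})

#: Canonical key for branch lengths; the spaced spelling is accepted on read.
BRANCH_LENGTH_KEY = "branch_length"
_BRANCH_LENGTH_ALIASES = (BRANCH_LENGTH_KEY, "branch length")

_EDGE_CORE_KEYS = ("id", "source", "target")


@dataclass
class PhyloGraph:
    """A phylogenetic tree (or ARG) as explicit vertex and edge sets."""

    vertices: list[dict[str, Any]] = field(default_factory=list)
    edges: list[dict[str, Any]] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_dict(self, lengths_on: str = "vertices") -> dict[str, Any]:
        """Plain-JSON form of the graph.

        ``lengths_on="edges"`` moves each branch length from the child
        vertex onto its incoming edge, for interoperability with graph
        conventions (NeXML keeps lengths on edges).
        """
        if lengths_on not in ("vertices", "edges"):
            raise ValueError(f"lengths_on must be 'vertices' or 'edges', got {lengths_on!r}")
        if lengths_on == "vertices":
            return {"vertices": [dict(v) for v in self.vertices],
                    "edges": [dict(e) for e in self.edges]}
        lengths = {v["id"]: v[BRANCH_LENGTH_KEY]
                   for v in self.vertices if BRANCH_LENGTH_KEY in v}
        vertices = [{k: v for k, v in vert.items() if k != BRANCH_LENGTH_KEY}
                    for vert in self.vertices]
        edges = []
        for e in self.edges:
            e = dict(e)
            if e["target"] in lengths:
                e[BRANCH_LENGTH_KEY] = lengths[e["target"]]
            edges.append(e)
        return {"vertices": vertices, "edges": edges}

    @classmethod
    def from_dict(cls, obj: dict[str, Any], metadata: dict[str, Any] | None = None) -> "PhyloGraph":
        """Read a graph from its JSON form, normalizing branch-length spelling
        and accepting lengths stored on either vertices or edges."""
        if "vertices" not in obj or "edges" not in obj:
            raise GraphError("graph object must contain 'vertices' and 'edges' sets")
        vertices = []
        by_id: dict[str, dict[str, Any]] = {}
        for vert in obj["vertices"]:
            v = dict(vert)
            for alias in _BRANCH_LENGTH_ALIASES[1:]:
                if alias in v:
                    v[BRANCH_LENGTH_KEY] = v.pop(alias)
            vertices.append(v)
            by_id[v["id"]] = v
        edges = []
        for edge in obj["edges"]:
            e = dict(edge)
            for alias in _BRANCH_LENGTH_ALIASES:
                if alias in e:
                    length = e.pop(alias)
                    target = by_id.get(e.get("target"))
                    if target is not None:
                        target.setdefault(BRANCH_LENGTH_KEY, length)
            edges.append(e)
        return cls(vertices=vertices, edges=edges, metadata=dict(metadata or {}))


def validate_graph(graph: PhyloGraph, *, arg: bool = False) -> str:
    """Check structural invariants; return the root vertex id.

    Default mode enforces tree-ness: unique ids, |E| == |V|-1, exactly one
    root (no incoming edge), every other vertex exactly one incoming edge,
    connected.  ``arg=True`` relaxes to a rooted connected DAG (multiple
    incoming edges allowed, no cycles).
    """
    ids = [v["id"] for v in graph.vertices]
    id_set = set(ids)
    if len(ids) != len(id_set):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise GraphError(f"duplicate vertex ids: {dupes}")
    edge_ids = [e["id"] for e in graph.edges]
    if len(edge_ids) != len(set(edge_ids)):
        dupes = sorted({i for i in edge_ids if edge_ids.count(i) > 1})
        raise GraphError(f"duplicate edge ids: {dupes}")
    indegree = {i: 0 for i in id_set}
    children: dict[str, list[str]] = {i: [] for i in id_set}
    for e in graph.edges:
        src, tgt = e.get("source"), e.get("target")
        if src not in id_set or tgt not in id_set:
            raise GraphError(f"edge {e.get('id')!r} references unknown vertex "
                             f"({src!r} -> {tgt!r})")
        indegree[tgt] += 1
        children[src].append(tgt)
    roots = [i for i in ids if indegree[i] == 0]
    if len(roots) != 1:
        raise GraphError(f"expected exactly one root vertex, found {roots!r}")
    if not arg:
        multi = [i for i in ids if indegree[i] > 1]
        if multi:
            raise GraphError(f"vertices with multiple parents (not a tree): {multi}")
        if len(graph.edges) != len(graph.vertices) - 1:
            raise GraphError(
                f"|edges| = {len(graph.edges)} but |vertices|-1 = {len(graph.vertices) - 1}")
    # reachability + cycle check from the root
    seen: set[str] = set()
    state: dict[str, int] = {}

    def visit(v: str, stack: tuple[str, ...]) -> None:
        if v in stack:
            raise GraphError(f"cycle through vertex {v!r}")
        if state.get(v) == 2:
            return
        seen.add(v)
        state[v] = 1
        for c in children[v]:
            visit(c, stack + (v,))
        state[v] = 2

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, len(ids) * 2 + 100))
    try:
        visit(roots[0], ())
    finally:
        sys.setrecursionlimit(old_limit)
    unreachable = id_set - seen
    if unreachable:
        raise GraphError(f"vertices unreachable from root: {sorted(unreachable)}")
    return roots[0]


def tree_to_graph(tree: dendropy.Tree) -> PhyloGraph:
    """Encode a rooted tree as a vertex/edge graph.

    Ids are assigned deterministically by preorder traversal (``v0``,
    ``v1``, ... / ``e0``, ...) so serialization is byte-stable.  Branch
    lengths land on the child vertex of each branch; the root gets one
    only if the input carries it.  Metadata attached to a branch (a
    ``bon_metadata`` dict on the dendropy edge) travels onto the edge.
    """
    leaf_names = [lf.taxon.label if lf.taxon is not None else lf.label
                  for lf in tree.leaf_node_iter()]
    leaf_names = [n for n in leaf_names if n is not None]
    dupes = sorted({n for n in leaf_names if leaf_names.count(n) > 1})
    if dupes:
        raise GraphError(f"duplicate leaf labels: {dupes}")
    graph = PhyloGraph()
    node_ids: dict[int, str] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        vid = f"v{i}"
        node_ids[id(node)] = vid
        vertex: dict[str, Any] = {"id": vid}
        name = node.taxon.label if node.taxon is not None else node.label
        if name is not None:
            vertex["name"] = name
        if node.edge is not None and node.edge.length is not None:
            vertex[BRANCH_LENGTH_KEY] = node.edge.length
        graph.vertices.append(vertex)
    e = 0
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            edge: dict[str, Any] = {"id": f"e{e}",
                                    "source": node_ids[id(node)],
                                    "target": node_ids[id(child)]}
            meta = getattr(child.edge, "bon_metadata", None)
            if meta:
                edge.update(meta)
            graph.edges.append(edge)
            e += 1
    return graph


def graph_to_tree(graph: PhyloGraph) -> dendropy.Tree:
    """Rebuild a dendropy tree from a graph; inverse of :func:`tree_to_graph`
    up to vertex/edge id relabeling."""
    root_id = validate_graph(graph)
    by_id = {v["id"]: v for v in graph.vertices}
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: dict[str, dendropy.Node] = {vid: dendropy.Node() for vid in by_id}
    children: dict[str, list[str]] = {vid: [] for vid in by_id}
    for e in graph.edges:
        children[e["source"]].append(e["target"])
        meta = {k: v for k, v in e.items() if k not in _EDGE_CORE_KEYS}
        if meta:
            nodes[e["target"]].edge.bon_metadata = meta
    for vid, node in nodes.items():
        vert = by_id[vid]
        if BRANCH_LENGTH_KEY in vert:
            node.edge.length = vert[BRANCH_LENGTH_KEY]
    tree.seed_node = nodes[root_id]
    stack = [root_id]
    while stack:
        vid = stack.pop()
        for cid in children[vid]:
            nodes[vid].add_child(nodes[cid])
            stack.append(cid)
    for vid, node in nodes.items():
        name = by_id[vid].get("name")
        if name is None:
            continue
        if node.is_leaf():
            node.taxon = tns.require_taxon(label=name)
        else:
            node.label = name
    return tree


# ---------------------------------------------------------------------------
# Newick round-trip helpers

def parse_newick(text: str) -> dendropy.Tree:
    """Parse one Newick tree (branch lengths after ':', quoted labels allowed)."""
    try:
        return dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"malformed Newick: {exc}") from exc


def write_newick(tree: dendropy.Tree) -> str:
    """Canonical one-line Newick with branch lengths where present.

    Labels that need it (spaces, punctuation) are quoted so that
    ``parse_newick(write_newick(t))`` preserves every label verbatim.
    """
    return tree.as_string(schema="newick", preserve_spaces=True,
                          unquoted_underscores=True,
                          suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# BON conversion

def trees_to_bon(trees: Iterable[dendropy.Tree],
                 spec: CompressionSpec = PHYLO_DEFAULT_SPEC,
                 metadata: Sequence[dict[str, Any]] | None = None) -> BonBlock:
    """One BON object per tree: {"tree": graph, **tree_metadata}.

    The header counts trees, not their nested vertices/edges.  With the
    default spec the whole graph is compressed into a single base64
    string while the metadata beside it stays readable.
    """
    trees = list(trees)
    metadata = list(metadata) if metadata is not None else [{} for _ in trees]
    if len(metadata) != len(trees):
        raise ValueError("need one metadata mapping per tree")
    payload: list[BonObject] = []
    for tree, meta in zip(trees, metadata):
        obj: BonObject = {"tree": tree_to_graph(tree).to_dict()}
        for k, v in meta.items():
            if k == "tree":
                raise ValueError("'tree' is reserved for the graph itself")
            obj[k] = v
        payload.append(obj)
    return encode_block(payload, spec)


def nexml_to_bon(nexml: str, spec: CompressionSpec = PHYLO_DEFAULT_SPEC) -> BonBlock:
    """Convert every tree of a NeXML document into one BON block."""
    try:
        trees = dendropy.TreeList.get(data=nexml, schema="nexml")
    except Exception as exc:
        raise FormatError(f"malformed NeXML: {exc}") from exc
    metadata = [{"name": t.label} if t.label else {} for t in trees]
    return trees_to_bon(trees, spec, metadata)


def bon_to_trees(block: BonBlock) -> list[tuple[dendropy.Tree, dict[str, Any]]]:
    """Decode every payload object back to (tree, metadata) pairs."""
    out = []
    for i, obj in enumerate(block.payload):
        rec = decode_object(obj, block.header, object_index=i)
        if "tree" not in rec:
            raise FormatError(f"object {i} lacks the mandatory 'tree' attribute")
        meta = {k: v for k, v in rec.items() if k != "tree"}
        graph = PhyloGraph.from_dict(rec["tree"], metadata=meta)
        out.append((graph_to_tree(graph), meta))
    return out


def bon_to_nexml(block: BonBlock) -> str:
    """Export a block of tree objects as a NeXML document."""
    tns = dendropy.TaxonNamespace()
    tree_list = dendropy.TreeList(taxon_namespace=tns)
    for tree, meta in bon_to_trees(block):
        migrated = dendropy.Tree.get(data=write_newick(tree), schema="newick",
                                     taxon_namespace=tns, preserve_underscores=True)
        if meta.get("name"):
            migrated.label = str(meta["name"])
        tree_list.append(migrated)
    return tree_list.as_string(schema="nexml")
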