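"""File formats: annotated Newick forests, TSV edge lists, JSON histories.

Forests are stored as Newick, one tree per line, with NHX tags carrying the
leaf state: ``name[&&NHX:S=species:P=1]`` (P=1 Present, P=0 Absent) and an
optional ``G=`` homology-group tag on roots.  Branch lengths, when present,
populate the real-valued existence intervals: a node is created when its
parent duplicates (t_c = accumulated length of the ancestors' branches) and
duplicates at t_c plus its own branch length; Present leaves persist to the
present (t_d = ∞).
"""

from __future__ import annotations

import json
import math
from typing import Optional, TextIO, Union

import dendropy

from .core import (DuplicationForest, FlipEdge, InteractionGraph,
                   NetworkHistory, TreeNode)
from .errors import FormatError

PathLike = Union[str, "os.PathLike[str]"]


# ---------------------------------------------------------------------------
# Forests
# ---------------------------------------------------------------------------

def _parse_nhx(comments: list[str], where: str) -> dict[str, str]:
    tags: dict[str, str] = {}
    for comment in comments:
        if not comment.startswith("&&NHX"):
            continue
        for part in comment.split(":")[1:]:
            if "=" not in part:
                raise FormatError(f"malformed NHX tag {part!r} at {where}")
            k, v = part.split("=", 1)
            tags[k] = v
    return tags


def read_forest(path: PathLike) -> DuplicationForest:
    """Read a duplication forest (Newick, one tree per line, NHX leaf tags)."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True,
                                  extract_comment_metadata=True)
    forest = DuplicationForest()
    for ti, tree in enumerate(trees):
        _read_tree(forest, tree, ti)
    forest.validate()
    return forest


def _node_label(nd: "dendropy.Node") -> Optional[str]:
    if nd.taxon is not None:
        return nd.taxon.label
    return nd.label


def _read_tree(forest: DuplicationForest, tree: "dendropy.Tree", ti: int) -> None:
    anon = [0]

    def walk(nd, parent_id, group, t_c):
        label = _node_label(nd)
        tags = {}
        if parent_id is None:
            # on a bare single-leaf tree the tag attaches to the tree itself
            tags.update({a.name: a.value for a in tree.annotations})
        tags.update({a.name: a.value for a in nd.annotations})
        tags.update(_parse_nhx(nd.comments, label or f"tree {ti}"))
        if parent_id is None and "G" in tags:
            group = tags["G"]
        nid = label
        if nid is None:
            nid = f"t{ti}.i{anon[0]}"
            anon[0] += 1
        if group is None:
            group = nid if parent_id is None else None
        children = nd.child_nodes()
        if len(children) not in (0, 2):
            raise FormatError(f"non-binary node {nid!r} "
                              f"({len(children)} children)")
        length = nd.edge.length
        t_d: Optional[float]
        if t_c is not None and length is not None:
            t_d = t_c + length
        else:
            t_d = None
        node = TreeNode(id=nid, parent=parent_id,
                        present=tags.get("P", "1") != "0",
                        homology_group=group, species=tags.get("S"),
                        t_c=t_c, t_d=t_d)
        forest.add_node(node, is_root=parent_id is None)
        if children:
            kids = [walk(c, nid, group, t_d) for c in children]
            node.left, node.right = kids[0], kids[1]
        elif node.present:
            node.t_d = math.inf if t_c is not None else None
        return nid

    seed = tree.seed_node
    # "((a,b)r);" yields an anonymous unifurcation above r: collapse it
    while len(seed.child_nodes()) == 1 and _node_label(seed) is None:
        seed = seed.child_nodes()[0]
    root_tc = 0.0 if any(nd.edge.length is not None
                         for nd in tree.preorder_node_iter()) else None
    walk(seed, None, None, root_tc)


def _nhx(parts: dict[str, str]) -> str:
    if not parts:
        return ""
    inner = ":".join(f"{k}={v}" for k, v in parts.items())
    return f"[&&NHX:{inner}]"


def _write_node(forest: DuplicationForest, nid: str, is_root: bool) -> str:
    node = forest[nid]
    tags: dict[str, str] = {}
    if node.is_leaf:
        if node.species is not None:
            tags["S"] = node.species
        tags["P"] = "1" if node.present else "0"
        body = node.id
    else:
        left = _write_node(forest, node.left, False)
        right = _write_node(forest, node.right, False)
        body = f"({left},{right}){node.id}"
    if is_root and node.homology_group not in (None, node.id):
        tags["G"] = node.homology_group
    length = ""
    if node.t_c is not None and node.t_d is not None and math.isfinite(node.t_d):
        length = f":{node.t_d - node.t_c:g}"
    return f"{body}{length}{_nhx(tags)}"


def write_forest(forest: DuplicationForest, path: PathLike) -> None:
    """Write a forest as Newick, one tree per line (round-trips with
    :func:`read_forest`)."""
    with open(path, "w") as fh:
        for r in sorted(forest.roots):
            fh.write(_write_node(forest, r, True) + ";\n")


# ---------------------------------------------------------------------------
# Graphs
# ---------------------------------------------------------------------------

def read_graph(path: PathLike) -> InteractionGraph:
    """TSV edge list with header ``#directed=0|1 selfloops=0|1``; one- column
    lines declare isolated nodes."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise FormatError("missing '#directed=.. selfloops=..' header")
        opts = dict(part.split("=", 1) for part in header[1:].split())
        try:
            directed = bool(int(opts["directed"]))
            selfloops = bool(int(opts["selfloops"]))
        except (KeyError, ValueError) as exc:
            raise FormatError(f"bad graph header {header!r}") from exc
        G = InteractionGraph(directed=directed, selfloops=selfloops)
        edges: list[tuple[str, str]] = []
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                G.add_node(cols[0])
            elif len(cols) == 2:
                for c in cols:
                    G.add_node(c)
                edges.append((cols[0], cols[1]))
            else:
                raise FormatError(f"line {ln}: expected 1 or 2 columns")
        seen = set()
        for u, v in edges:
            key = (u, v) if directed else frozenset((u, v))
            if key in seen:
                raise FormatError(f"duplicate edge ({u}, {v})")
            seen.add(key)
            G.add_edge(u, v)
    return G


def write_graph(G: InteractionGraph, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"#directed={int(G.directed)} selfloops={int(G.selfloops)}\n")
        touched = set()
        for u, v in sorted(G.g.edges):
            fh.write(f"{u}\t{v}\n")
            touched.update((u, v))
        for u in sorted(G.nodes - touched):
            fh.write(f"{u}\n")


# ---------------------------------------------------------------------------
# Histories
# ---------------------------------------------------------------------------

def history_to_json(history: NetworkHistory, **extra) -> dict:
    """JSON-serializable envelope for a set of flip edges (forest separate)."""
    flips = [{"a": f.a, "b": f.b, "orientation": f.orientation,
              **({"t": f.t} if f.t is not None else {})}
             for f in history.flips]
    return {"directed": history.directed, "selfloops": history.selfloops,
            "flips": flips, **extra}


def history_from_json(obj: dict, forest: DuplicationForest) -> NetworkHistory:
    flips = [FlipEdge(d["a"], d["b"], d.get("orientation", "undirected"),
                      d.get("t")) for d in obj["flips"]]
    return NetworkHistory(forest, flips, directed=bool(obj.get("directed")),
                          selfloops=bool(obj.get("selfloops")))


def write_json(obj: dict, fh_or_path: Union[PathLike, TextIO]) -> None:
    if hasattr(fh_or_path, "write"):
        json.dump(obj, fh_or_path, indent=2, default=float)
        fh_or_path.write("\n")
    else:
        with open(fh_or_path, "w") as fh:
            json.dump(obj, fh, indent=2, default=float)
            fh.write("\n")
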