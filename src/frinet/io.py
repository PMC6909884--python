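"""Reading and writing trees, networks, and cluster lists.

Supported formats:

* **Newick** (read): standard rooted dialect, arbitrary degree; branch
  lengths and internal labels are accepted and ignored.
* **eNewick** (read/write): extended Newick where every hybrid node appears
  once in full and elsewhere as a ``#H<i>`` stub.
* **Graphviz DOT** (write-only): for quick figures.
* **Cluster list** (read/write): one cluster per line, taxa separated by
  commas or whitespace; ``#`` starts a comment; an optional ``taxa:`` header
  fixes the universe.
"""

from __future__ import annotations

import re

from .clusters import META_PREFIX, ClusterSet
from .errors import ParseError
from .network import PhyloNetwork

__all__ = [
    "read_cluster_file",
    "read_enewick",
    "read_newick",
    "write_cluster_file",
    "write_dot",
    "write_enewick",
]

_LABEL_RE = re.compile(r"[^(),;:\s\[\]]+")


class _Scanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def _linecol(self) -> tuple[int, int]:
        head = self.text[: self.pos]
        line = head.count("\n") + 1
        col = self.pos - (head.rfind("\n") + 1) + 1
        return line, col

    def error(self, msg: str) -> ParseError:
        line, col = self._linecol()
        return ParseError(msg, line, col)

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self, ch: str) -> None:
        if self.peek() != ch:
            raise self.error(f"expected {ch!r}, found {self.peek()!r}")
        self.pos += 1

    def label(self) -> str:
        self.skip_ws()
        m = _LABEL_RE.match(self.text, self.pos)
        if not m:
            return ""
        self.pos = m.end()
        return m.group()


def _parse_one(sc: _Scanner, net: PhyloNetwork,
               hybrids: dict[str, int]) -> int:
    """Recursive descent for one (e)Newick node; returns its node id."""
    if sc.peek() == "(":
        sc.take("(")
        kids = [_parse_one(sc, net, hybrids)]
        while sc.peek() == ",":
            sc.take(",")
            kids.append(_parse_one(sc, net, hybrids))
        sc.take(")")
        name = sc.label()
        v = _named_node(sc, net, hybrids, name, internal=True)
        for w in kids:
            net.add_edge(v, w)
    else:
        name = sc.label()
        if not name:
            raise sc.error("expected a taxon label")
        v = _named_node(sc, net, hybrids, name, internal=False)
    if sc.peek() == ":":  # branch length: parsed, ignored
        sc.take(":")
        if not sc.label():
            raise sc.error("expected a branch length after ':'")
    return v


def _named_node(sc: _Scanner, net: PhyloNetwork, hybrids: dict[str, int],
                name: str, internal: bool) -> int:
    hid = None
    if "#" in name:
        name, tag = name.split("#", 1)
        hid = tag
        if not hid:
            raise sc.error("empty hybrid tag after '#'")
    if hid is not None:
        if hid in hybrids:
            return hybrids[hid]
        v = net.new_node(label=name or None)
        hybrids[hid] = v
        return v
    if not internal:
        if name.startswith(META_PREFIX):
            raise sc.error(f"leaf label may not start with {META_PREFIX!r}")
        return net.new_node(label=name)
    return net.new_node()  # internal names are ignored


def read_newick(text: str) -> list[PhyloNetwork]:
    """Parse one or more semicolon-terminated rooted trees.

    Raises :class:`~frinet.errors.ParseError` (with line/column) on malformed
    input or duplicate leaf labels.
    """
    trees = read_enewick(text)
    for t in trees:
        if not t.is_tree():
            raise ParseError("input contains reticulations; expected plain trees")
    return trees


def read_enewick(text: str) -> list[PhyloNetwork]:
    """Parse semicolon-terminated networks in ``#H`` hybrid-stub notation."""
    sc = _Scanner(text)
    out = []
    while True:
        sc.skip_ws()
        if sc.pos >= len(sc.text):
            break
        net = PhyloNetwork()
        hybrids: dict[str, int] = {}
        _parse_one(sc, net, hybrids)
        sc.take(";")
        try:
            net.validate()
        except ValueError as exc:
            raise sc.error(str(exc)) from None
        out.append(net)
    if not out:
        raise ParseError("no tree found in input", 1, 1)
    return out


def write_enewick(n: PhyloNetwork) -> str:
    """Serialize a network; each reticulation appears once in full and as
    ``#H<i>`` stubs at its other parents."""
    ids = {v: i + 1 for i, v in enumerate(n.reticulations())}
    seen: set[int] = set()

    def emit(v: int) -> str:
        if v in ids and v in seen:
            return f"#H{ids[v]}"
        seen.add(v)
        kids = n.children(v)
        if kids:
            body = "(" + ",".join(emit(w) for w in kids) + ")"
        else:
            body = n.label(v) or ""
        if v in ids:
            body += f"#H{ids[v]}"
        return body

    return emit(n.root) + ";"


def write_dot(n: PhyloNetwork) -> str:
    """Graphviz DOT text; reticulation nodes are drawn as boxes."""
    lines = ["digraph N {", "  rankdir=TB;", "  node [shape=point];"]
    for v in n.nodes():
        lab = n.label(v)
        if lab is not None:
            lines.append(f'  n{v} [shape=none, label="{lab}"];')
        elif n.g.in_degree(v) >= 2:
            lines.append(f"  n{v} [shape=box, width=0.08, height=0.08];")
    for u, v in n.edges():
        lines.append(f"  n{u} -> n{v};")
    lines.append("}")
    return "\n".join(lines) + "\n"


_SPLIT_RE = re.compile(r"[,\s]+")


def read_cluster_file(text: str) -> ClusterSet:
    """Parse a cluster-list file; line order fixes the taxa encounter order."""
    universe = None
    orders = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("taxa:"):
            universe = [t for t in _SPLIT_RE.split(line[5:].strip()) if t]
            continue
        members = [t for t in _SPLIT_RE.split(line) if t]
        for t in members:
            if t.startswith(META_PREFIX):
                raise ParseError(
                    f"taxon label may not start with {META_PREFIX!r}", lineno, 1)
        orders.append(tuple(members))
    try:
        return ClusterSet(orders, universe=universe)
    except ValueError as exc:
        raise ParseError(str(exc), 1, 1) from None


def write_cluster_file(y: ClusterSet) -> str:
    lines = ["taxa: " + " ".join(y.taxa)]
    lines += [" ".join(o) for o in y.cluster_orders]
    return "\n".join(lines) + "\n"
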