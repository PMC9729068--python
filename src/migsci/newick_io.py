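"""Read and write species networks as annotated extended Newick strings.

Dialect
-------
A network is written as a rooted tree in which every hybrid node (a node
with two parents) appears twice: once with its subtree, and once as a bare
reference.  Hybrid labels contain a ``#`` (e.g. ``H#1``), as in the usual
extended-Newick convention.

Every node occurrence may carry a bracketed annotation block::

    ((A[&age=0,theta=0.002], H#1[&age=0.001,theta=0.002,phi=0.2])S[&age=0.002,theta=0.01],
     (B[&age=0,theta=0.01])H#1[&theta=0.01,phi=0.8])R[&age=0.004,theta=0.01];

Recognized keys:

``age``
    node age (required on the first occurrence of each node; tips default
    to 0).
``theta``
    population size of the branch from this node occurrence to its parent
    in the surrounding text; on the root, the root population size.
``phi``
    probability of the corresponding parent edge (hybrid occurrences only).
``samples``
    number of sequences sampled from a tip (defaults to 1 on tips).
``mig``
    migration bands received by this branch, encoded as
    ``donor/M/start/end`` and joined with ``+`` when there are several.

The writer emits this same dialect, so ``parse(write(net)) == net``.
"""

from __future__ import annotations

import math
import re

from .params import MigrationBand, NetEdge, NetNode, SpeciesNetwork

__all__ = ["parse_species_network", "write_species_network", "NewickParseError"]


class NewickParseError(ValueError):
    """Malformed extended-Newick input."""


_LABEL_RE = re.compile(r"[A-Za-z0-9_.#\-]+")


class _Tokenizer:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def _skip_ws(self):
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        self._skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self, ch: str):
        self._skip_ws()
        if self.peek() != ch:
            raise NewickParseError(
                f"expected {ch!r} at position {self.pos}: "
                f"...{self.text[self.pos:self.pos + 25]!r}"
            )
        self.pos += 1

    def label(self) -> str:
        self._skip_ws()
        m = _LABEL_RE.match(self.text, self.pos)
        if not m:
            raise NewickParseError(f"expected a node label at position {self.pos}")
        self.pos = m.end()
        return m.group()

    def annotations(self) -> dict[str, str]:
        self._skip_ws()
        if self.peek() != "[":
            return {}
        end = self.text.find("]", self.pos)
        if end < 0:
            raise NewickParseError("unterminated annotation block")
        block = self.text[self.pos + 1 : end].lstrip("&")
        self.pos = end + 1
        out = {}
        for item in block.split(","):
            if not item.strip():
                continue
            if "=" not in item:
                raise NewickParseError(f"bad annotation item {item!r}")
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
        return out


def _parse_bands(recipient: str, spec: str) -> list[MigrationBand]:
    bands = []
    for part in spec.split("+"):
        fields = part.split("/")
        if len(fields) != 4:
            raise NewickParseError(
                f"bad mig annotation {part!r} on node {recipient!r}; "
                "expected donor/M/start/end"
            )
        donor, M, start, end = fields
        bands.append(MigrationBand(donor, recipient, float(M), float(start), float(end)))
    return bands


def parse_species_network(text: str) -> SpeciesNetwork:
    """Parse an annotated extended-Newick string into a :class:`SpeciesNetwork`.

    Raises :class:`NewickParseError` for malformed text, duplicate hybrid
    subtrees, or age/structure violations (the error names the offending
    node).
    """
    tok = _Tokenizer(text)
    nodes: dict[str, NetNode] = {}
    ages: dict[str, float] = {}
    edges: dict[tuple[str, str], NetEdge] = {}
    samples: dict[str, int] = {}
    bands: list[MigrationBand] = []
    hybrid_subtree_seen: set[str] = set()
    root_theta: list[float] = []

    def parse_subtree(parent: str | None) -> str:
        children: list[str] = []
        has_subtree = tok.peek() == "("
        if has_subtree:
            tok.take("(")
            while True:
                pass_label = parse_subtree(None)  # placeholder; fixed below
                children.append(pass_label)
                if tok.peek() == ",":
                    tok.take(",")
                else:
                    break
            tok.take(")")
        label = tok.label()
        ann = tok.annotations()
        is_hybrid = "#" in label

        if has_subtree and is_hybrid:
            if label in hybrid_subtree_seen:
                raise NewickParseError(
                    f"hybrid node {label!r} carries a subtree more than once"
                )
            hybrid_subtree_seen.add(label)

        if "age" in ann:
            age = float(ann["age"])
            if label in ages and ages[label] != age:
                raise NewickParseError(f"conflicting ages for node {label!r}")
            ages[label] = age
        elif not has_subtree and not is_hybrid:
            ages.setdefault(label, 0.0)

        if label not in nodes and label in ages:
            nodes[label] = NetNode(label, ages[label])

        if "mig" in ann:
            bands.extend(_parse_bands(label, ann["mig"]))
        if "samples" in ann:
            samples[label] = int(ann["samples"])

        for ch in children:
            # fix up parent links now that this node's label is known; the
            # most recent unconsumed occurrence of ch belongs to this parent
            if (ch, label) in edges:
                raise NewickParseError(f"duplicate edge {ch!r} -> {label!r}")
            ch_theta, ch_phi = _pending[ch].pop()
            if not _pending[ch]:
                del _pending[ch]
            edges[(ch, label)] = NetEdge(ch, label, ch_theta, ch_phi)

        theta = float(ann["theta"]) if "theta" in ann else None
        phi = float(ann["phi"]) if "phi" in ann else None
        if theta is None:
            raise NewickParseError(f"node {label!r}: missing theta annotation")
        _pending.setdefault(label, []).append((theta, phi))
        return label

    # per-label stack of edge attributes whose parent is not yet known
    _pending: dict[str, list[tuple[float, float | None]]] = {}

    root = parse_subtree(None)
    if tok.peek() != ";":
        raise NewickParseError("expected ';' at end of network string")
    theta, phi = _pending.pop(root)[-1]
    if phi is not None:
        raise NewickParseError(f"root {root!r} cannot carry a phi annotation")
    root_theta.append(theta)
    if _pending:
        raise NewickParseError(f"dangling hybrid references: {sorted(_pending)}")

    missing = [lab for lab in ages if lab not in nodes]
    if missing:
        raise NewickParseError(f"nodes without ages: {missing}")

    # tips default to one sample; ghost tips must be annotated explicitly
    net_tmp = SpeciesNetwork(nodes, edges, root, root_theta[0], {}, tuple(bands))
    tip_samples = {t: samples.get(t, 1) for t in net_tmp.tips()}
    net = SpeciesNetwork(nodes, edges, root, root_theta[0], tip_samples, tuple(bands))

    for (c, p), e in edges.items():
        if e.phi is None and nodes[c].age >= nodes[p].age:
            raise NewickParseError(
                f"node {c!r} (age {nodes[c].age}) is not younger than its "
                f"parent {p!r} (age {nodes[p].age})"
            )
    problems = net.validate()
    if problems:
        raise NewickParseError("; ".join(problems))
    return net


def _fmt(x: float) -> str:
    return repr(float(x))


def write_species_network(net: SpeciesNetwork) -> str:
    """Serialize a :class:`SpeciesNetwork` to the extended-Newick dialect.

    The serialization is deterministic (children in sorted label order,
    hybrid subtrees attached under the lexicographically first parent) and
    round-trips losslessly through :func:`parse_species_network`.
    """
    bands_by_recipient: dict[str, list[MigrationBand]] = {}
    for b in net.bands:
        bands_by_recipient.setdefault(b.recipient, []).append(b)

    def annot(label: str, edge: NetEdge | None) -> str:
        items = [f"age={_fmt(net.nodes[label].age)}"]
        if edge is None:
            items.append(f"theta={_fmt(net.root_theta)}")
        else:
            items.append(f"theta={_fmt(edge.theta)}")
            if edge.phi is not None:
                items.append(f"phi={_fmt(edge.phi)}")
        if label in bands_by_recipient:
            migs = "+".join(
                f"{b.donor}/{_fmt(b.M)}/{_fmt(b.start)}/{_fmt(b.end)}"
                for b in sorted(bands_by_recipient[label], key=lambda b: b.donor)
            )
            items.append(f"mig={migs}")
        if label in net.samples:
            items.append(f"samples={net.samples[label]}")
        return "[&" + ",".join(items) + "]"

    def expanding_parent(label: str) -> str:
        # hybrid subtree is written under its first parent (sorted order)
        return sorted(e.parent for e in net.parents_of(label))[0]

    def render(label: str, parent: str | None) -> str:
        edge = None
        if parent is not None:
            edge = net.edges[(label, parent)]
        kids = sorted(net.children_of(label))
        expand = parent is None or len(net.parents_of(label)) == 1 or (
            expanding_parent(label) == parent
        )
        if kids and expand:
            inner = ",".join(render(k, label) for k in kids)
            return f"({inner}){label}{annot(label, edge)}"
        return f"{label}{annot(label, edge)}"

    return render(net.root, None) + ";"
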