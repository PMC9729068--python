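"""Structured-coalescent simulation of gene trees and JC sequences.

Gene genealogies are simulated backward in time on a species network:
within each epoch (the interval between consecutive network node ages or
migration-band endpoints) every pair of lineages in a population coalesces
at rate ``2/theta`` and every lineage in the recipient branch of an active
migration band jumps to the donor branch at rate ``w = 4*M/theta_recipient``
(the backward counterpart of forward migration at ``M`` migrants per
generation).  At a hybrid node each lineage in the recipient branch picks
the introgressing parent independently with probability ``phi``.  Event
times are exact competing exponentials truncated at epoch boundaries; no
time discretization is involved.

Sequences evolve along the resulting gene tree under the JC model with
branch lengths in expected mutations per site, i.i.d. across sites, the
root sequence uniform over {A, C, G, T}.

Per-locus random streams are seeded by ``(seed, locus_index)`` so datasets
are reproducible and earlier loci are unchanged when ``L`` grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .likelihood import LocusCount, jc_mismatch_prob, write_counts_tsv
from .params import ScenarioSpec, SpeciesNetwork

__all__ = [
    "GeneTreeNode",
    "GeneTree",
    "CompiledNetwork",
    "simulate_gene_tree",
    "evolve_sequences_jc",
    "pairwise_diff_counts",
    "MultilocusDataset",
    "simulate_dataset",
    "write_phylip",
    "write_fasta",
    "write_gene_trees",
]

_BASES = np.array(list("ACGT"))


@dataclass
class GeneTreeNode:
    """Node of a simulated genealogy.

    ``pop_path`` records, for the lineage starting at this node, the
    populations visited on the way to the parent as ``(entry_age, branch
    label)`` pairs -- including migration-band jumps and hybrid-node
    choices.
    """

    name: str
    age: float
    children: list["GeneTreeNode"] = field(default_factory=list)
    pop_path: list[tuple[float, str]] = field(default_factory=list)

    def is_tip(self) -> bool:
        return not self.children


@dataclass
class GeneTree:
    root: GeneTreeNode
    n_migrations: int = 0

    def tips(self) -> list[GeneTreeNode]:
        out = []

        def walk(nd):
            if nd.is_tip():
                out.append(nd)
            for ch in nd.children:
                walk(ch)

        walk(self.root)
        return out

    def coalescent_ages(self) -> list[float]:
        out = []

        def walk(nd):
            if not nd.is_tip():
                out.append(nd.age)
            for ch in nd.children:
                walk(ch)

        walk(self.root)
        return sorted(out)

    def mrca_age(self, name1: str, name2: str) -> float:
        """Age of the most recent common ancestor of two named tips."""

        def find_path(nd, name, acc):
            if nd.name == name and nd.is_tip():
                return acc + [nd]
            for ch in nd.children:
                r = find_path(ch, name, acc + [nd])
                if r:
                    return r
            return None

        p1 = find_path(self.root, name1, [])
        p2 = find_path(self.root, name2, [])
        if p1 is None or p2 is None:
            raise KeyError(f"tip not found: {name1!r} or {name2!r}")
        common = [a for a, b in zip(p1, p2) if a is b]
        return common[-1].age

    def to_newick(self) -> str:
        def render(nd):
            if nd.is_tip():
                return nd.name
            inner = ",".join(
                f"{render(ch)}:{nd.age - ch.age:.10g}" for ch in nd.children
            )
            return f"({inner})"

        return render(self.root) + ";"


# ---------------------------------------------------------------------------
# network compilation and the structured coalescent
# ---------------------------------------------------------------------------

_ROOT_POP = ("__root__", None)


class CompiledNetwork:
    """Event-ready form of a species network, reusable across loci."""

    def __init__(self, net: SpeciesNetwork):
        bad = net.validate()
        if bad:
            raise ValueError("invalid SpeciesNetwork: " + "; ".join(bad))
        self.net = net
        self.age = {lab: nd.age for lab, nd in net.nodes.items()}
        # population = edge, keyed (child, parent); plus the root population
        self.theta = {key: e.theta for key, e in net.edges.items()}
        self.theta[_ROOT_POP] = net.root_theta
        self.span = {
            (c, p): (self.age[c], self.age[p]) for (c, p) in net.edges
        }
        self.span[_ROOT_POP] = (self.age[net.root], math.inf)
        # out-edges of each node, with hybrid choice probabilities
        self.out_edges: dict[str, list[tuple[tuple[str, str], float]]] = {}
        for lab in net.nodes:
            if lab == net.root:
                self.out_edges[lab] = [(_ROOT_POP, 1.0)]
            else:
                self.out_edges[lab] = [
                    ((e.child, e.parent), e.phi if e.phi is not None else 1.0)
                    for e in net.parents_of(lab)
                ]
        # unique branch -> population key lookup for migration bands
        branch_pop: dict[str, tuple[str, str]] = {}
        for (c, p) in net.edges:
            branch_pop.setdefault(c, (c, p))
        self.bands = [
            (branch_pop[b.donor], branch_pop[b.recipient],
             4.0 * b.M / self.theta[branch_pop[b.recipient]], b.start, b.end)
            for b in net.bands
        ]
        cuts = set(self.age.values())
        for b in net.bands:
            cuts.update((b.start, b.end))
        self.epochs = sorted(cuts)
        self.sample_tips = [
            (tip, k) for tip, k in sorted(net.samples.items()) if k > 0
        ]

    def simulate(self, rng: np.random.Generator) -> GeneTree:
        age = self.age
        lineages: list[tuple[tuple[str, str], GeneTreeNode]] = []
        for tip, k in self.sample_tips:
            pop = None  # tip's initial out-edge; hybrids never start as tips
            (pop, _), = self.out_edges[tip][:1] or [((None, None), 1.0)]
            for i in range(k):
                nd = GeneTreeNode(f"{tip}_{i + 1}", age[tip])
                nd.pop_path.append((age[tip], pop[0]))
                lineages.append((pop, nd))
        n_mig = 0
        epochs = self.epochs + [math.inf]
        t = 0.0
        ei = 0
        while len(lineages) > 1:
            # advance to the first epoch containing t
            while epochs[ei + 1] <= t:
                ei += 1
            t_end = epochs[ei + 1]
            # promote lineages whose population has ended by t
            moved = True
            while moved:
                moved = False
                for idx, (pop, nd) in enumerate(lineages):
                    if self.span[pop][1] <= t and pop != _ROOT_POP:
                        top = pop[1]
                        outs = self.out_edges[top]
                        if len(outs) == 1:
                            new_pop = outs[0][0]
                        else:
                            probs = [w for _, w in outs]
                            choice = rng.choice(len(outs), p=probs)
                            new_pop = outs[choice][0]
                        nd.pop_path.append((t, new_pop[0] if new_pop[1] else "root"))
                        lineages[idx] = (new_pop, nd)
                        moved = True
            # rates within this epoch
            counts: dict[tuple, list[int]] = {}
            for idx, (pop, _) in enumerate(lineages):
                counts.setdefault(pop, []).append(idx)
            coal_rates = []
            for pop, idxs in counts.items():
                k = len(idxs)
                coal_rates.append((pop, k * (k - 1) / self.theta[pop]))
            mig_rates = []
            for donor, recip, w, s, e in self.bands:
                if s <= t and t_end <= e and recip in counts:
                    mig_rates.append((donor, recip, w * len(counts[recip])))
            total = sum(r for _, r in coal_rates) + sum(r for *_, r in mig_rates)
            if total <= 0:
                t = t_end
                continue
            dt = rng.exponential(1.0 / total)
            if t + dt >= t_end:
                t = t_end
                continue
            t += dt
            u = rng.uniform(0, total)
            acc = 0.0
            event = None
            for pop, r in coal_rates:
                acc += r
                if u < acc:
                    event = ("coal", pop)
                    break
            if event is None:
                for donor, recip, r in mig_rates:
                    acc += r
                    if u < acc:
                        event = ("mig", donor, recip)
                        break
            if event[0] == "coal":
                idxs = counts[event[1]]
                i1, i2 = rng.choice(len(idxs), size=2, replace=False)
                a, b = sorted((idxs[i1], idxs[i2]))
                popk = event[1]
                parent = GeneTreeNode("", t, [lineages[a][1], lineages[b][1]])
                parent.pop_path.append((t, popk[0] if popk[1] else "root"))
                lineages[a] = (popk, parent)
                del lineages[b]
            else:
                _, donor, recip = event
                idxs = counts[recip]
                pick = idxs[rng.integers(len(idxs))]
                nd = lineages[pick][1]
                nd.pop_path.append((t, donor[0]))
                lineages[pick] = (donor, nd)
                n_mig += 1
        return GeneTree(lineages[0][1], n_migrations=n_mig)


def simulate_gene_tree(network: SpeciesNetwork | CompiledNetwork,
                       rng: np.random.Generator) -> GeneTree:
    """Draw one gene genealogy from the structured coalescent on a network."""
    cn = network if isinstance(network, CompiledNetwork) else CompiledNetwork(network)
    return cn.simulate(rng)


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def evolve_sequences_jc(tree: GeneTree, n: int, rng: np.random.Generator
                        ) -> dict[str, np.ndarray]:
    """Evolve ``n`` sites along a gene tree under JC.

    Returns tip name -> array of base indices (0..3).  Branch lengths are
    age differences, in expected mutations per site; each site mutates to
    one of the three other bases with total probability
    ``(3/4)(1 - e^{-4b/3})`` along a branch of length ``b``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out: dict[str, np.ndarray] = {}
    root_seq = rng.integers(0, 4, size=n, dtype=np.int8)

    stack = [(tree.root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node.is_tip():
            out[node.name] = seq
            continue
        for ch in node.children:
            b = node.age - ch.age
            p_change = 0.75 * -math.expm1(-4.0 * b / 3.0)
            child_seq = seq.copy()
            hit = rng.random(n) < p_change
            k = int(hit.sum())
            if k:
                child_seq[hit] = (
                    child_seq[hit] + rng.integers(1, 4, size=k, dtype=np.int8)
                ) % 4
            stack.append((ch, child_seq))
    return out


def pairwise_diff_counts(alignment: dict[str, np.ndarray], name1: str,
                         name2: str) -> LocusCount:
    """Count mismatching sites between two sequences of an alignment."""
    s1, s2 = alignment[name1], alignment[name2]
    if len(s1) != len(s2):
        raise ValueError("sequences have unequal lengths")
    return LocusCount(int(np.sum(s1 != s2)), len(s1))


# ---------------------------------------------------------------------------
# multilocus datasets
# ---------------------------------------------------------------------------


@dataclass
class MultilocusDataset:
    """Simulated loci: alignments and/or per-locus pairwise counts."""

    scenario: str
    seed: int
    L: int
    S: int
    n: int
    alignments: list[dict[str, np.ndarray]] | None = None
    counts: list[LocusCount] | None = None
    trees: list[GeneTree] | None = None


def _locus_rng(seed: int, locus: int) -> np.random.Generator:
    return np.random.default_rng([seed, locus])


def simulate_dataset(
    scenario: ScenarioSpec,
    seed: int | None = None,
    emit: str = "alignments",
    pair: tuple[str, str] = ("A", "B"),
    keep_trees: bool = False,
) -> MultilocusDataset:
    """Simulate a multilocus dataset under a scenario.

    ``emit``:

    - ``"alignments"`` -- evolve full JC sequences at every locus;
    - ``"counts"`` -- record only the pairwise difference count between the
      first sequences of the two species in ``pair``, drawing
      ``x ~ Binomial(n, p(t))`` from the pair's coalescent time ``t``
      (exactly the JC distribution of differences for a two-tip tree);
    - ``"both"`` -- alignments plus counts (counts computed from the
      sequences).

    Loci are independent with per-locus substreams keyed by
    ``(seed, locus)``; a fixed seed reproduces the dataset exactly.
    """
    bad = scenario.validate()
    if bad:
        raise ValueError("invalid scenario: " + "; ".join(bad))
    if emit not in ("alignments", "counts", "both"):
        raise ValueError(f"unknown emit mode {emit!r}")
    seed = scenario.seed if seed is None else seed
    net = scenario.resolved_network()
    cn = CompiledNetwork(net)
    alignments = [] if emit in ("alignments", "both") else None
    counts = [] if emit in ("counts", "both") else None
    trees = [] if keep_trees else None
    t1, t2 = f"{pair[0]}_1", f"{pair[1]}_1"
    for locus in range(scenario.L):
        rng = _locus_rng(seed, locus)
        tree = cn.simulate(rng)
        if keep_trees:
            trees.append(tree)
        if emit in ("alignments", "both"):
            aln = evolve_sequences_jc(tree, scenario.n, rng)
            alignments.append(aln)
            if emit == "both":
                counts.append(pairwise_diff_counts(aln, t1, t2))
        else:
            t = tree.mrca_age(t1, t2)
            x = int(rng.binomial(scenario.n, jc_mismatch_prob(t)))
            counts.append(LocusCount(x, scenario.n))
    return MultilocusDataset(
        scenario=scenario.name, seed=seed, L=scenario.L, S=scenario.S,
        n=scenario.n, alignments=alignments, counts=counts, trees=trees,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_phylip(dataset: MultilocusDataset, path) -> None:
    """Multilocus sequential PHYLIP, one block per locus."""
    if dataset.alignments is None:
        raise ValueError("dataset holds no alignments")
    path = Path(path)
    with path.open("w") as fh:
        for aln in dataset.alignments:
            names = sorted(aln)
            fh.write(f"{len(names)} {dataset.n}\n")
            for nm in names:
                fh.write(f"{nm}  {''.join(_BASES[aln[nm]])}\n")
            fh.write("\n")


def write_fasta(alignment: dict[str, np.ndarray], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for nm in sorted(alignment):
            fh.write(f">{nm}\n{''.join(_BASES[alignment[nm]])}\n")


def write_gene_trees(trees: list[GeneTree], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for tr in trees:
            fh.write(tr.to_newick() + "\n")


def write_dataset_counts(dataset: MultilocusDataset, path) -> None:
    if dataset.counts is None:
        raise ValueError("dataset holds no counts")
    write_counts_tsv(dataset.counts, path)
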