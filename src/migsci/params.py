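"""Parameterizations of two-species gene-flow models and multi-species networks.

Two families of models are covered:

* **MSC-M** (multispecies coalescent with migration): continuous gene flow
  from species A to species B at a rate of ``M`` migrants per generation.
  Three variants differ only in when gene flow is active:

  - ``IM``  -- migration throughout ``(0, tau_R)``;
  - ``IIM`` -- isolation with initial migration, active on ``(tau_T, tau_R)``;
  - ``SC``  -- secondary contact, active on ``(0, tau_T)``.

* **MSci** (multispecies coalescent with introgression): gene flow collapsed
  to a single pulse at time ``tau_S``, where each B lineage jumps to the
  donor side with probability ``phi``.

All times (``tau``) and population sizes (``theta = 4*N*mu``) are measured in
expected mutations per site; time 0 is the present and increases into the
past.  The coalescent rate for a pair of lineages in a population of size
``theta`` is ``2/theta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "THETA0",
    "THETA1",
    "MSCMParams",
    "MSciParams",
    "NetNode",
    "NetEdge",
    "MigrationBand",
    "SpeciesNetwork",
    "ScenarioSpec",
    "preset_scenario",
    "PRESET_NAMES",
    "validate",
    "two_species_network",
    "msci_two_species_network",
]

#: population size used for the "thin" branches of the study scenarios
THETA0 = 0.002
#: population size used for the "thick" branches of the study scenarios
THETA1 = 0.01


@dataclass(frozen=True)
class MSCMParams:
    """Two-species isolation-with-migration model (variants IM, IIM, SC).

    Parameters
    ----------
    variant
        One of ``"IM"``, ``"IIM"``, ``"SC"``.
    tau_R
        Species divergence time (root age).
    tau_T
        Secondary time point: end of gene flow (IIM) or start of contact
        (SC).  Must be 0 for the plain IM model.
    theta_A, theta_B, theta_T, theta_R
        Population sizes of the A branch, the B branch, the ghost branch on
        the B side above/below ``tau_T``, and the root population.
    M
        Population migration rate from A to B, in migrants per generation.
    """

    variant: str
    tau_R: float
    tau_T: float
    theta_A: float
    theta_B: float
    theta_T: float
    theta_R: float
    M: float

    @property
    def w(self) -> float:
        """Mutation-scaled migration rate, ``w = 4*M/theta_B``.

        This is the backward-in-time jump rate of a B lineage into A; the
        pairwise coalescent density depends on ``M`` and ``theta_B`` only
        through ``w``.
        """
        return 4.0 * self.M / self.theta_B

    @property
    def delta_tau(self) -> float:
        """Duration of the gene-flow period."""
        if self.variant == "IM":
            return self.tau_R
        if self.variant == "IIM":
            return self.tau_R - self.tau_T
        return self.tau_T  # SC

    @property
    def t_min_support(self) -> float:
        """Smallest possible pairwise coalescent time (0 except for IIM)."""
        return self.tau_T if self.variant == "IIM" else 0.0

    def validate(self) -> list[str]:
        v = []
        if self.variant not in ("IM", "IIM", "SC"):
            v.append(f"variant: unknown variant {self.variant!r}")
        for name in ("theta_A", "theta_B", "theta_T", "theta_R"):
            if not getattr(self, name) > 0:
                v.append(f"{name}: population sizes must be positive")
        if not 0 <= self.tau_T < self.tau_R:
            v.append("tau_T: requires 0 <= tau_T < tau_R")
        if self.M < 0:
            v.append("M: migration rate must be nonnegative")
        if self.variant == "IM" and self.tau_T != 0:
            v.append("tau_T: must be 0 under the IM variant")
        return v


@dataclass(frozen=True)
class MSciParams:
    """Two-species introgression (MSci) model.

    At time ``tau_S`` each B lineage jumps, with probability ``phi``, into
    the donor population S on the A side; the pair can then coalesce in S
    at rate ``2/theta_S`` before the species join at the root ``tau_R``.

    With one sequence per species per locus, only ``(tau_R, tau_S, theta_R,
    theta_S, phi)`` are identifiable; ``theta_A``, ``theta_B`` and
    ``theta_H`` (the B-side branch above the introgression node) are
    irrelevant to the pairwise coalescent density and may be left ``None``.
    """

    tau_R: float
    tau_S: float
    theta_R: float
    theta_S: float
    phi: float
    theta_A: float | None = None
    theta_B: float | None = None
    theta_H: float | None = None

    #: parameters identifiable from pairwise (one sequence per species) data
    IDENTIFIABLE = ("tau_R", "tau_S", "theta_R", "theta_S", "phi")

    def validate(self) -> list[str]:
        v = []
        if not 0 <= self.tau_S < self.tau_R:
            v.append("tau_S: requires 0 <= tau_S < tau_R")
        for name in ("theta_R", "theta_S"):
            if not getattr(self, name) > 0:
                v.append(f"{name}: population sizes must be positive")
        for name in ("theta_A", "theta_B", "theta_H"):
            val = getattr(self, name)
            if val is not None and not val > 0:
                v.append(f"{name}: population sizes must be positive")
        if not 0 <= self.phi <= 1:
            v.append("phi: introgression probability must be in [0, 1]")
        return v


# ---------------------------------------------------------------------------
# species networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetNode:
    """A node of a species network: a species-tree node or a hybrid node."""

    label: str
    age: float


@dataclass(frozen=True)
class NetEdge:
    """A branch of the species network, identified by its child node.

    ``theta`` is the population size of the branch between ``child`` and
    ``parent``.  A hybrid (introgression) node has two out-edges; ``phi``
    is the probability that a lineage reaching the child node follows this
    edge (``None`` on ordinary edges).
    """

    child: str
    parent: str
    theta: float
    phi: float | None = None


@dataclass(frozen=True)
class MigrationBand:
    """Continuous migration from branch ``donor`` to branch ``recipient``.

    ``M`` is the population migration rate (migrants per generation,
    forward in time); the band is active over the age interval
    ``(start, end)``.  Backward in time, each lineage in the recipient
    branch jumps to the donor at rate ``4*M/theta_recipient``.
    """

    donor: str
    recipient: str
    M: float
    start: float
    end: float


@dataclass(frozen=True)
class SpeciesNetwork:
    """Species phylogeny with optional introgression nodes and migration bands.

    ``nodes`` maps labels to :class:`NetNode`; ``edges`` is keyed by
    ``(child, parent)``.  ``root_theta`` is the population size of the root
    population (above the root node).  ``samples`` gives the number of
    sequences sampled per tip species (ghost tips have 0).
    """

    nodes: dict[str, NetNode]
    edges: dict[tuple[str, str], NetEdge]
    root: str
    root_theta: float
    samples: dict[str, int]
    bands: tuple[MigrationBand, ...] = ()

    def __post_init__(self):
        # canonical band order so equality is representation-independent
        ordered = tuple(
            sorted(self.bands, key=lambda b: (b.donor, b.recipient, b.start))
        )
        object.__setattr__(self, "bands", ordered)

    def parents_of(self, label: str) -> list[NetEdge]:
        return [e for (c, _), e in self.edges.items() if c == label]

    def children_of(self, label: str) -> list[str]:
        return [c for (c, p) in self.edges if p == label]

    def tips(self) -> list[str]:
        return [lab for lab in self.nodes if not self.children_of(lab)]

    def hybrids(self) -> list[str]:
        return [lab for lab in self.nodes if len(self.parents_of(lab)) == 2]

    def validate(self) -> list[str]:
        v = []
        for (c, p), e in self.edges.items():
            if c not in self.nodes:
                v.append(f"edge {c}->{p}: unknown child node {c!r}")
                continue
            if p not in self.nodes:
                v.append(f"edge {c}->{p}: unknown parent node {p!r}")
                continue
            # hybrid edges may be horizontal (equal ages); others are strict
            strict = e.phi is None
            ages_ok = (
                self.nodes[c].age < self.nodes[p].age
                if strict
                else self.nodes[c].age <= self.nodes[p].age
            )
            if not ages_ok:
                v.append(
                    f"edge {c}->{p}: child age {self.nodes[c].age} not below "
                    f"parent age {self.nodes[p].age}"
                )
            if not e.theta > 0:
                v.append(f"edge {c}->{p}: theta must be positive")
        if not self.root_theta > 0:
            v.append("root_theta: must be positive")
        for lab in self.nodes:
            par = self.parents_of(lab)
            if lab == self.root:
                if par:
                    v.append(f"node {lab}: root must have no parent")
            elif len(par) == 1:
                if par[0].phi is not None:
                    v.append(f"node {lab}: phi set on a non-hybrid edge")
            elif len(par) == 2:
                phis = sorted(e.phi for e in par if e.phi is not None)
                if len(phis) != 2 or abs(sum(phis) - 1.0) > 1e-12:
                    v.append(f"node {lab}: hybrid edge phis must sum to 1")
                if any(not 0 <= f <= 1 for f in phis):
                    v.append(f"node {lab}: phi must be in [0, 1]")
            else:
                v.append(f"node {lab}: unreachable node (no parent, not root)")
        for b in self.bands:
            for lab in (b.donor, b.recipient):
                if lab not in self.nodes:
                    v.append(f"band {b.donor}->{b.recipient}: unknown branch {lab!r}")
            if b.M < 0:
                v.append(f"band {b.donor}->{b.recipient}: M must be nonnegative")
            if not b.start < b.end:
                v.append(f"band {b.donor}->{b.recipient}: empty time interval")
            # a band can only connect branches that coexist during its interval
            for lab in (b.donor, b.recipient):
                if lab not in self.nodes:
                    continue
                lo = self.nodes[lab].age
                hi = self._branch_top(lab)
                if b.start < lo - 1e-15 or b.end > hi + 1e-15:
                    v.append(
                        f"band {b.donor}->{b.recipient}: interval "
                        f"({b.start}, {b.end}) outside branch {lab} "
                        f"lifetime ({lo}, {hi})"
                    )
        for s, k in self.samples.items():
            if s not in self.nodes or self.children_of(s):
                v.append(f"samples: {s!r} is not a tip")
            elif k < 0:
                v.append(f"samples: negative count for {s!r}")
        return v

    def _branch_top(self, label: str) -> float:
        if label == self.root:
            return math.inf
        return max(self.nodes[e.parent].age for e in self.parents_of(label))


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """A named simulation scenario: model plus dataset dimensions."""

    name: str
    L: int
    S: int
    n: int
    mscm: MSCMParams | None = None
    msci: MSciParams | None = None
    network: SpeciesNetwork | None = None
    seed: int = 0
    replicates: int = 1

    def validate(self) -> list[str]:
        v = []
        for nm in ("L", "S", "n", "replicates"):
            if getattr(self, nm) < 1:
                v.append(f"{nm}: must be a positive integer")
        nmodels = sum(x is not None for x in (self.mscm, self.msci, self.network))
        if nmodels != 1:
            v.append("exactly one of mscm/msci/network must be set")
        elif self.mscm is not None:
            v.extend(self.mscm.validate())
        elif self.msci is not None:
            v.extend(self.msci.validate())
        else:
            v.extend(self.network.validate())
        return v

    def resolved_network(self) -> SpeciesNetwork:
        """The network to simulate from (two-species params are converted)."""
        if self.network is not None:
            return self.network
        if self.mscm is not None:
            return two_species_network(self.mscm, samples=self.S)
        return msci_two_species_network(self.msci, samples=self.S)


def validate(obj) -> list[str]:
    """Collect invariant violations for any model/parameter object.

    Returns an empty list iff the object is valid; violations are strings
    naming the offending field and rule.
    """
    return obj.validate()


# ---------------------------------------------------------------------------
# two-species network builders
# ---------------------------------------------------------------------------


def two_species_network(p: MSCMParams, samples: int = 1) -> SpeciesNetwork:
    """Species network for a two-species MSC-M model (any variant).

    For IIM and SC a ghost node ``T`` is placed on the B branch at
    ``tau_T`` (carrying ``theta_T`` above it), mirroring the ghost-species
    device used to define those models.
    """
    nodes = {
        "A": NetNode("A", 0.0),
        "B": NetNode("B", 0.0),
        "R": NetNode("R", p.tau_R),
    }
    edges = {
        ("A", "R"): NetEdge("A", "R", p.theta_A),
    }
    if p.variant == "IM":
        edges[("B", "R")] = NetEdge("B", "R", p.theta_B)
        bands = (MigrationBand("A", "B", p.M, 0.0, p.tau_R),)
    else:
        nodes["T"] = NetNode("T", p.tau_T)
        edges[("B", "T")] = NetEdge("B", "T", p.theta_B)
        edges[("T", "R")] = NetEdge("T", "R", p.theta_T)
        if p.variant == "IIM":
            bands = (MigrationBand("A", "T", p.M, p.tau_T, p.tau_R),)
        else:  # SC
            bands = (MigrationBand("A", "B", p.M, 0.0, p.tau_T),)
    return SpeciesNetwork(
        nodes=nodes,
        edges=edges,
        root="R",
        root_theta=p.theta_R,
        samples={"A": samples, "B": samples},
        bands=bands,
    )


def msci_two_species_network(p: MSciParams, samples: int = 1) -> SpeciesNetwork:
    """Species network for the two-species MSci model.

    Node ``S`` sits on the A branch and hybrid node ``H`` on the B branch,
    both at ``tau_S``; a B lineage reaching ``H`` enters the donor branch
    ``S -> R`` with probability ``phi`` and otherwise continues on the B
    side (branch ``H -> R`` with ``theta_H``).
    """
    th_A = p.theta_A if p.theta_A is not None else p.theta_S
    th_B = p.theta_B if p.theta_B is not None else p.theta_S
    th_H = p.theta_H if p.theta_H is not None else p.theta_S
    nodes = {
        "A": NetNode("A", 0.0),
        "B": NetNode("B", 0.0),
        "S": NetNode("S", p.tau_S),
        "H": NetNode("H", p.tau_S),
        "R": NetNode("R", p.tau_R),
    }
    edges = {
        ("A", "S"): NetEdge("A", "S", th_A),
        ("S", "R"): NetEdge("S", "R", p.theta_S),
        ("B", "H"): NetEdge("B", "H", th_B),
        ("H", "S"): NetEdge("H", "S", p.theta_S, phi=p.phi),
        ("H", "R"): NetEdge("H", "R", th_H, phi=1.0 - p.phi),
    }
    return SpeciesNetwork(
        nodes=nodes,
        edges=edges,
        root="R",
        root_theta=p.theta_R,
        samples={"A": samples, "B": samples},
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _fig1(variant: str, M: float = 0.2) -> MSCMParams:
    # Thin/thick assignment: extant donor tip A is thin (theta0); the
    # recipient branch B, the ghost branch T and the root are thick
    # (theta1).  The time period of gene flow is theta0 in all variants;
    # tau_R for SC is not stated alongside the others and is taken as
    # 2*theta0 by symmetry with IIM.
    if variant == "IM":
        tau_R, tau_T = THETA0, 0.0
    else:
        tau_R, tau_T = 2 * THETA0, THETA0
    return MSCMParams(
        variant=variant,
        tau_R=tau_R,
        tau_T=tau_T,
        theta_A=THETA0,
        theta_B=THETA1,
        theta_T=THETA1,
        theta_R=THETA1,
        M=M,
    )


def _fig4_nodes(tau_T: float) -> dict[str, NetNode]:
    return {
        "A": NetNode("A", 0.0),
        "B": NetNode("B", 0.0),
        "C": NetNode("C", 0.0),
        "D": NetNode("D", 0.0),
        "T": NetNode("T", tau_T),
        "S": NetNode("S", 3 * THETA0),
        "R": NetNode("R", 4 * THETA0),
    }


def _fig4_base_edges(tau_T: float) -> dict[tuple[str, str], NetEdge]:
    # topology (((B, C)T, A)S, D)R; recipient-side branch B and the
    # ancestral branches are thick, the other tips thin
    return {
        ("B", "T"): NetEdge("B", "T", THETA1),
        ("C", "T"): NetEdge("C", "T", THETA0),
        ("T", "S"): NetEdge("T", "S", THETA1),
        ("A", "S"): NetEdge("A", "S", THETA0),
        ("S", "R"): NetEdge("S", "R", THETA1),
        ("D", "R"): NetEdge("D", "R", THETA0),
    }


def _fig4_msci_A() -> SpeciesNetwork:
    # episodic introgression A -> B at tau_X = tau_Y = 1.5*theta0
    tau_T, tau_h = 2 * THETA0, 1.5 * THETA0
    nodes = _fig4_nodes(tau_T)
    nodes["X"] = NetNode("X", tau_h)
    nodes["Y"] = NetNode("Y", tau_h)
    edges = _fig4_base_edges(tau_T)
    del edges[("B", "T")], edges[("A", "S")]
    edges[("B", "Y")] = NetEdge("B", "Y", THETA1)
    edges[("Y", "T")] = NetEdge("Y", "T", THETA1, phi=0.8)
    edges[("Y", "X")] = NetEdge("Y", "X", THETA0, phi=0.2)
    edges[("A", "X")] = NetEdge("A", "X", THETA0)
    edges[("X", "S")] = NetEdge("X", "S", THETA0)
    return SpeciesNetwork(
        nodes=nodes, edges=edges, root="R", root_theta=THETA1,
        samples={"A": 4, "B": 4, "C": 4, "D": 4},
    )


def _fig4_msci_B() -> SpeciesNetwork:
    # introgression assigned to the parental branch ST, at 1.5*theta0,
    # with tau_T lowered to theta0
    tau_T, tau_h = THETA0, 1.5 * THETA0
    nodes = _fig4_nodes(tau_T)
    nodes["X"] = NetNode("X", tau_h)
    nodes["Y"] = NetNode("Y", tau_h)
    edges = _fig4_base_edges(tau_T)
    del edges[("T", "S")], edges[("A", "S")]
    edges[("T", "Y")] = NetEdge("T", "Y", THETA1)
    edges[("Y", "S")] = NetEdge("Y", "S", THETA1, phi=0.8)
    edges[("Y", "X")] = NetEdge("Y", "X", THETA0, phi=0.2)
    edges[("A", "X")] = NetEdge("A", "X", THETA0)
    edges[("X", "S")] = NetEdge("X", "S", THETA0)
    return SpeciesNetwork(
        nodes=nodes, edges=edges, root="R", root_theta=THETA1,
        samples={"A": 4, "B": 4, "C": 4, "D": 4},
    )


def _fig4_im_C() -> SpeciesNetwork:
    # continuous migration A -> B over (0, tau_T) at M = 0.1
    tau_T = 2 * THETA0
    net = SpeciesNetwork(
        nodes=_fig4_nodes(tau_T),
        edges=_fig4_base_edges(tau_T),
        root="R",
        root_theta=THETA1,
        samples={"A": 4, "B": 4, "C": 4, "D": 4},
        bands=(MigrationBand("A", "B", 0.1, 0.0, tau_T),),
    )
    return net


def _fig4_im_D() -> SpeciesNetwork:
    # continuous migration A -> ST over (tau_T, tau_S) at M = 0.1
    tau_T = THETA0
    return SpeciesNetwork(
        nodes=_fig4_nodes(tau_T),
        edges=_fig4_base_edges(tau_T),
        root="R",
        root_theta=THETA1,
        samples={"A": 4, "B": 4, "C": 4, "D": 4},
        bands=(MigrationBand("A", "T", 0.1, tau_T, 3 * THETA0),),
    )


def _fig6_iim3() -> SpeciesNetwork:
    # three-species IIM: ((A, B)S, C)R with A -> B migration over
    # (tau_T, tau_S), specified through a ghost node U on the B branch
    tau_T = THETA0
    nodes = {
        "A": NetNode("A", 0.0),
        "B": NetNode("B", 0.0),
        "C": NetNode("C", 0.0),
        "U": NetNode("U", tau_T),
        "S": NetNode("S", 3 * THETA0),
        "R": NetNode("R", 4 * THETA0),
    }
    edges = {
        ("A", "S"): NetEdge("A", "S", THETA0),
        ("B", "U"): NetEdge("B", "U", THETA1),
        ("U", "S"): NetEdge("U", "S", THETA1),
        ("S", "R"): NetEdge("S", "R", THETA1),
        ("C", "R"): NetEdge("C", "R", THETA0),
    }
    return SpeciesNetwork(
        nodes=nodes, edges=edges, root="R", root_theta=THETA1,
        samples={"A": 4, "B": 4, "C": 4},
        bands=(MigrationBand("A", "U", 0.1, tau_T, 3 * THETA0),),
    )


def _fig7_ghost_intro(with_ghost_tip: bool = False) -> SpeciesNetwork:
    # introgression from the A lineage into B with tau_X > tau_Y: the
    # donor node X (age 1.5*theta0) connects to the hybrid node Y (age
    # theta0) through a bridge branch on the donor side.  With
    # ``with_ghost_tip`` the donor lineage is written as a ghost species U
    # splitting from A at tau_X; the sampled-species process is identical.
    nodes = {
        "A": NetNode("A", 0.0),
        "B": NetNode("B", 0.0),
        "C": NetNode("C", 0.0),
        "D": NetNode("D", 0.0),
        "Y": NetNode("Y", THETA0),
        "X": NetNode("X", 1.5 * THETA0),
        "T": NetNode("T", 2 * THETA0),
        "S": NetNode("S", 3 * THETA0),
        "R": NetNode("R", 4 * THETA0),
    }
    edges = {
        ("B", "Y"): NetEdge("B", "Y", THETA1),
        ("Y", "T"): NetEdge("Y", "T", THETA1, phi=0.8),
        ("Y", "X"): NetEdge("Y", "X", THETA0, phi=0.2),
        ("C", "T"): NetEdge("C", "T", THETA0),
        ("T", "S"): NetEdge("T", "S", THETA1),
        ("A", "X"): NetEdge("A", "X", THETA0),
        ("X", "S"): NetEdge("X", "S", THETA0),
        ("S", "R"): NetEdge("S", "R", THETA1),
        ("D", "R"): NetEdge("D", "R", THETA0),
    }
    samples = {"A": 4, "B": 4, "C": 4, "D": 4}
    if with_ghost_tip:
        # bridge rewritten as a ghost species U diverging from A at tau_X,
        # receiving the introgressing lineages at a junction G on its branch
        nodes["U"] = NetNode("U", 0.0)
        nodes["G"] = NetNode("G", THETA0)
        del edges[("Y", "X")]
        edges[("U", "G")] = NetEdge("U", "G", THETA0)
        edges[("G", "X")] = NetEdge("G", "X", THETA0)
        edges[("Y", "G")] = NetEdge("Y", "G", THETA0, phi=0.2)
        samples["U"] = 0
    return SpeciesNetwork(
        nodes=nodes, edges=edges, root="R", root_theta=THETA1, samples=samples
    )


def _fig8_ghost_mig() -> SpeciesNetwork:
    # two-step migration relay through an extinct ghost lineage:
    # C -> (ghost U branch) over (tau_U, tau_S), ghost -> B over
    # (tau_U, tau_T); species V below U are never sampled
    nodes = {
        "A": NetNode("A", 0.0),
        "B": NetNode("B", 0.0),
        "C": NetNode("C", 0.0),
        "V": NetNode("V", 0.0),
        "U": NetNode("U", THETA0),
        "T": NetNode("T", 2 * THETA0),
        "S": NetNode("S", 3 * THETA0),
        "R": NetNode("R", 4 * THETA0),
    }
    edges = {
        ("A", "T"): NetEdge("A", "T", THETA0),
        ("B", "T"): NetEdge("B", "T", THETA1),
        ("T", "S"): NetEdge("T", "S", THETA0),
        ("V", "U"): NetEdge("V", "U", THETA0),
        ("U", "S"): NetEdge("U", "S", THETA0),
        ("S", "R"): NetEdge("S", "R", THETA0),
        ("C", "R"): NetEdge("C", "R", THETA0),
    }
    return SpeciesNetwork(
        nodes=nodes, edges=edges, root="R", root_theta=THETA1,
        samples={"A": 4, "B": 4, "C": 4, "V": 0},
        bands=(
            MigrationBand("C", "U", 0.2, THETA0, 3 * THETA0),
            MigrationBand("U", "B", 0.2, THETA0, 2 * THETA0),
        ),
    )


def _presets() -> dict[str, ScenarioSpec]:
    return {
        "fig1-im": ScenarioSpec("fig1-im", L=4000, S=4, n=1000, mscm=_fig1("IM")),
        "fig1-iim": ScenarioSpec("fig1-iim", L=4000, S=4, n=1000, mscm=_fig1("IIM")),
        "fig1-sc": ScenarioSpec("fig1-sc", L=4000, S=4, n=1000, mscm=_fig1("SC")),
        "fig4-A": ScenarioSpec(
            "fig4-A", L=4000, S=4, n=500, network=_fig4_msci_A(), replicates=100
        ),
        "fig4-B": ScenarioSpec(
            "fig4-B", L=4000, S=4, n=500, network=_fig4_msci_B(), replicates=100
        ),
        "fig4-C": ScenarioSpec(
            "fig4-C", L=4000, S=4, n=500, network=_fig4_im_C(), replicates=100
        ),
        "fig4-D": ScenarioSpec(
            "fig4-D", L=4000, S=4, n=500, network=_fig4_im_D(), replicates=100
        ),
        "fig6-iim3": ScenarioSpec(
            "fig6-iim3", L=4000, S=4, n=500, network=_fig6_iim3(), replicates=100
        ),
        "fig7-ghost-intro": ScenarioSpec(
            "fig7-ghost-intro", L=4000, S=4, n=500,
            network=_fig7_ghost_intro(), replicates=100,
        ),
        "fig8-ghost-mig": ScenarioSpec(
            "fig8-ghost-mig", L=4000, S=4, n=500,
            network=_fig8_ghost_mig(), replicates=100,
        ),
    }


PRESET_NAMES = tuple(_presets())


def preset_scenario(name: str) -> ScenarioSpec:
    """Return the fully populated :class:`ScenarioSpec` for a named preset.

    Raises
    ------
    KeyError
        If ``name`` is not a known preset; the message lists valid names.
    """
    presets = _presets()
    if name not in presets:
        raise KeyError(
            f"unknown scenario {name!r}; available presets: "
            + ", ".join(sorted(presets))
        )
    return presets[name]
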