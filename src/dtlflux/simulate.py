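"""Synthetic data generation for gene-content evolution studies.

This module produces the inputs that, in the real study system, would
come from metagenome-assembled genomes of a DPANN-like archaeal clade:
a rooted species tree, gene families evolving by origination,
duplication, transfer and loss (DTL) along it with a ground-truth event
log, proteomes whose amino-acid composition carries a planted linear
optimal-growth-temperature (OGT) signal, and gene-coordinate
annotations with controlled coding density and gene overlap.

The DTL process is a continuous-time competing-exponential-clocks
model per gene copy per branch.  Transfers pick a donor copy and a
recipient uniformly among the other lineages alive at the event time,
so every transfer names an extant contemporaneous donor.  Copy number
is tracked internally; the exported matrix keeps counts and exposes a
binarised view.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .matrix import PresenceMatrix
from .tree import SpeciesTree, TreeNode

__all__ = [
    "DTLRates",
    "Event",
    "EventLog",
    "SyntheticProteomeSet",
    "GeneRecord",
    "SyntheticAnnotation",
    "InfeasibleConfigurationError",
    "simulate_species_tree",
    "simulate_clade_shift",
    "simulate_gene_content",
    "simulate_binary_gain_loss",
    "replay_event_log",
    "simulate_proteomes",
    "simulate_annotation",
    "assign_tip_ogts",
    "pick_disjoint_clades",
    "IVYWREL",
    "BASELINE_AA_FREQS",
]

EVENT_TYPES = ("D", "T", "L", "O")

IVYWREL = frozenset("IVYWREL")

# Typical prokaryotic proteome composition (renormalised to sum to 1);
# the default baseline the planted OGT signal perturbs.
_RAW_AA_FREQS: dict[str, float] = {
    "A": 0.078, "R": 0.052, "N": 0.042, "D": 0.053, "C": 0.010,
    "Q": 0.038, "E": 0.063, "G": 0.072, "H": 0.020, "I": 0.066,
    "L": 0.098, "K": 0.055, "M": 0.023, "F": 0.041, "P": 0.044,
    "S": 0.060, "T": 0.054, "W": 0.011, "Y": 0.033, "V": 0.069,
}
_RAW_TOTAL = sum(_RAW_AA_FREQS.values())
BASELINE_AA_FREQS: dict[str, float] = {
    aa: f / _RAW_TOTAL for aa, f in _RAW_AA_FREQS.items()
}


class InfeasibleConfigurationError(ValueError):
    """Requested synthetic layout cannot fit the stated constraints."""


@dataclass(frozen=True)
class DTLRates:
    """Per-family event rates, per unit branch length.

    ``origination`` applies per branch while the family is globally
    absent; the other three apply per extant gene copy.
    """

    origination: float = 0.0
    duplication: float = 0.0
    transfer: float = 0.0
    loss: float = 0.0

    def __post_init__(self):
        for name in ("origination", "duplication", "transfer", "loss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} rate must be >= 0")

    def scaled(self, multipliers: Mapping[str, float]) -> "DTLRates":
        vals = {}
        for name in ("origination", "duplication", "transfer", "loss"):
            m = multipliers.get(name, 1.0)
            if m <= 0:
                raise ValueError(f"multiplier for {name} must be > 0")
            vals[name] = getattr(self, name) * m
        return DTLRates(**vals)


@dataclass(frozen=True)
class Event:
    """One simulated or inferred gene-family event.

    ``branch`` is the node id below the edge the event happened on (for
    transfers: the recipient).  ``time`` is measured along that branch
    from its parent end.  ``donor`` is set iff ``type == "T"``.
    """

    family: str
    branch: str
    type: str
    donor: Optional[str]
    time: float

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if (self.donor is not None) != (self.type == "T"):
            raise ValueError("donor must be present iff the event is a transfer")


class EventLog:
    """Ordered record of DTL events plus the root state that seeds replay."""

    def __init__(self, events: list[Event], root_presence: dict[str, int]):
        self.events = events
        self.root_presence = root_presence

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def count(self, event_type: str) -> int:
        return sum(1 for e in self.events if e.type == event_type)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.family, e.branch, e.type, e.donor or "", e.time) for e in self.events],
            columns=["family", "branch", "type", "donor", "time"],
        )


@dataclass
class SyntheticProteomeSet:
    """Per-genome protein sequences with a known planted OGT signal."""

    sequences: dict[str, list[str]]
    true_ogt: dict[str, float]
    baseline_freqs: dict[str, float]
    slope: float

    def proteome(self, genome: str) -> list[str]:
        return self.sequences[genome]


@dataclass(frozen=True)
class GeneRecord:
    """A CDS interval, 0-based half-open, on one contig."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class SyntheticAnnotation:
    """Gene coordinates plus genome metadata for streamlining statistics."""

    genome_id: str
    contig: str
    length: int
    gc: float
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(f"gene [{g.start}, {g.end}) beyond contig end")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(n_tips: int, birth_rate: float, death_rate: float,
                          seed: int) -> SpeciesTree:
    """Simulate a rooted ultrametric species tree under birth-death.

    Uses the general sampling approach (a uniformly chosen time slice of
    a larger simulated tree), which guarantees strictly positive
    terminal branch lengths.  Tips are labelled ``t1..tN`` and internal
    nodes ``n{preorder index}``, deterministically for a fixed seed.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not birth_rate > death_rate >= 0:
        raise ValueError("require birth_rate > death_rate >= 0")
    dtree = None
    last_error = None
    # dendropy's GSA sampler can fail on unlucky histories (whole-tree
    # extinction during pruning); retry with deterministically derived
    # sub-seeds so a fixed seed still yields a fixed tree
    for attempt in range(100):
        rng = _random.Random(int(seed) + 1_000_003 * attempt)
        try:
            dtree = treesim.birth_death_tree(
                birth_rate=float(birth_rate), death_rate=float(death_rate),
                num_extant_tips=int(n_tips),
                gsa_ntax=max(2 * int(n_tips), n_tips + 2),
                rng=rng,
            )
            break
        except (TypeError, ValueError, IndexError) as exc:
            last_error = exc
    if dtree is None:  # pragma: no cover - would need 100 failures
        raise RuntimeError(f"birth-death sampling failed: {last_error}")
    tree = SpeciesTree.from_dendropy(dtree)
    # deterministic relabelling by preorder position
    mapping: dict[str, str] = {}
    tip_no = 0
    for i, nid in enumerate(tree.preorder()):
        if tree.is_tip(nid):
            tip_no += 1
            mapping[nid] = f"t{tip_no}"
        else:
            mapping[nid] = f"n{i}"
    nodes = [
        TreeNode(
            id=mapping[nid],
            parent=None if tree.parent(nid) is None else mapping[tree.parent(nid)],
            length=tree.length(nid),
            is_tip=tree.is_tip(nid),
        )
        for nid in tree.preorder()
    ]
    return SpeciesTree(nodes)


def pick_disjoint_clades(tree: SpeciesTree, labels: Sequence[str],
                         min_tips: int = 2,
                         target_fraction: float = 0.25) -> dict[str, str]:
    """Label disjoint clades on a tree.

    Each label is assigned to the unclaimed proper clade whose tip count
    is closest to ``target_fraction`` of all tips (at least
    ``min_tips``, never the full tip set, never overlapping a
    previously claimed clade), so a background of unlabelled lineages
    always remains.  Ties prefer the smaller clade, then the earlier
    node id.  Returns label -> clade-root node id.  Deterministic.
    """
    claimed: set[str] = set()
    assignment: dict[str, str] = {}
    n_total = len(tree.tips)
    target = target_fraction * n_total
    for label in labels:
        candidates = []
        for nid in tree.preorder():
            if tree.is_tip(nid) or nid == tree.root or nid in claimed:
                continue
            sub = tree.subtree(nid)
            if any(s in claimed for s in sub):
                continue
            n_sub = sum(1 for s in sub if tree.is_tip(s))
            if n_sub < min_tips or n_sub >= n_total - len(
                    {s for s in claimed if tree.is_tip(s)}):
                continue
            candidates.append((abs(n_sub - target), n_sub, nid, sub))
        if not candidates:
            raise InfeasibleConfigurationError(
                f"no disjoint clade with >= {min_tips} tips left for {label!r}"
            )
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        _, _, nid, sub = candidates[0]
        tree.label_clade(label, nid)
        claimed.update(sub)
        assignment[label] = nid
    return assignment


# ---------------------------------------------------------------------------
# gene-content evolution
# ---------------------------------------------------------------------------

RateSchedule = Union[DTLRates, Mapping[str, DTLRates]]


def simulate_clade_shift(tree: SpeciesTree, base_rates: DTLRates,
                         shifted_clade: str,
                         multipliers: Mapping[str, float]) -> dict[str, DTLRates]:
    """Branch-indexed rate schedule with a rate shift inside one clade.

    Branches inside the labelled clade (stem branch included) use
    ``base_rates`` scaled by ``multipliers``; all other branches use
    ``base_rates`` unchanged.
    """
    inside = set(tree.clade_nodes(shifted_clade))  # KeyError if unknown
    shifted = base_rates.scaled(multipliers)
    return {
        nid: (shifted if nid in inside else base_rates)
        for nid in tree.preorder()
    }


def _epochs(tree: SpeciesTree):
    """Time-slices of the tree: (t_start, t_end, edges live in slice).

    An edge (identified by its child node id) is live on the half-open
    interval (time(parent), time(child)].  The root itself is not an
    edge.
    """
    times = sorted({tree.time(nid) for nid in tree.preorder()})
    slices = []
    for t0, t1 in zip(times, times[1:]):
        live = [
            nid for nid in tree.preorder()
            if tree.parent(nid) is not None
            and tree.time(tree.parent(nid)) <= t0 and tree.time(nid) >= t1
        ]
        slices.append((t0, t1, live))
    return slices


def _as_schedule(tree: SpeciesTree, rates: RateSchedule) -> dict[str, DTLRates]:
    if isinstance(rates, DTLRates):
        return {nid: rates for nid in tree.preorder()}
    missing = [nid for nid in tree.preorder() if nid not in rates]
    if missing:
        raise ValueError(f"rate schedule missing branches: {missing[:5]}")
    return dict(rates)


def simulate_gene_content(tree: SpeciesTree, rates: RateSchedule,
                          n_families: int, root_presence_prob: float,
                          seed: int) -> tuple[PresenceMatrix, EventLog]:
    """Evolve gene families along the tree under the DTL process.

    Each family evolves independently.  Within a time slice of the tree
    the set of live lineages is constant and events follow competing
    exponential clocks: per copy, duplication and loss at the branch's
    rates; per branch, origination while the family has no copies
    anywhere.  The transfer rate is indexed by the *recipient* branch
    (a clade-specific transfer shift therefore models gene influx into
    that clade): branch b receives transfers at rate
    ``t_b * (copies elsewhere) / (n_live - 1)``, with the donor drawn
    copy-weighted from the other live lineages, so a transfer always
    names an extant contemporaneous donor.  With a uniform transfer
    rate this is equivalent to a per-copy donor clock with a uniform
    recipient.  Transfers are silently impossible while a single
    lineage is alive.  At a speciation both daughter edges inherit the
    parental copy number.

    Returns the (copy-count) presence matrix over tips and the exact
    event log; replaying the log from the root states reproduces the
    matrix.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not 0.0 <= root_presence_prob <= 1.0:
        raise ValueError("root_presence_prob must be in [0, 1]")
    schedule = _as_schedule(tree, rates)
    rng = np.random.default_rng(int(seed))
    slices = _epochs(tree)
    tips = tree.tips
    width = max(4, len(str(n_families)))
    families = [f"fam{i + 1:0{width}d}" for i in range(n_families)]

    counts = np.zeros((n_families, len(tips)), dtype=int)
    tip_idx = {t: j for j, t in enumerate(tips)}
    events: list[Event] = []
    root_presence: dict[str, int] = {}
    children_of_root = tree.children(tree.root)

    for fi, fam in enumerate(families):
        root_copies = 1 if rng.random() < root_presence_prob else 0
        root_presence[fam] = root_copies
        copies: dict[str, int] = {}
        # the root speciates at time 0: both daughter edges inherit
        for c in children_of_root:
            copies[c] = root_copies
        for t0, t1, live in slices:
            # close edges ending at t0, open edges starting at t0
            for nid in list(copies):
                if tree.time(nid) <= t0 and nid not in live:
                    k = copies.pop(nid)
                    if tree.is_tip(nid):
                        counts[fi, tip_idx[nid]] = k
                    else:
                        for c in tree.children(nid):
                            copies[c] = k
            for nid in live:
                copies.setdefault(nid, 0)
            t = t0
            n_live = len(live)
            while True:
                total_copies = sum(copies.values())
                per_edge: list[tuple[str, float]] = []
                for nid in live:
                    r = schedule[nid]
                    k = copies[nid]
                    rate = k * (r.duplication + r.loss)
                    if n_live > 1:
                        # transfer INTO this branch, fed by copies elsewhere
                        rate += r.transfer * (total_copies - k) / (n_live - 1)
                    if total_copies == 0:
                        rate += r.origination
                    per_edge.append((nid, rate))
                total_rate = sum(rate for _, rate in per_edge)
                if total_rate <= 0:
                    break
                t_next = t + rng.exponential(1.0 / total_rate)
                if t_next >= t1:
                    break
                t = t_next
                u = rng.random() * total_rate
                acc = 0.0
                edge = per_edge[-1][0]
                for nid, rate in per_edge:
                    acc += rate
                    if u < acc:
                        edge = nid
                        break
                r = schedule[edge]
                k = copies[edge]
                w_d = k * r.duplication
                w_l = k * r.loss
                w_t = (r.transfer * (total_copies - k) / (n_live - 1)
                       if n_live > 1 else 0.0)
                w_o = r.origination if total_copies == 0 else 0.0
                v = rng.random() * (w_d + w_l + w_t + w_o)
                rel = t - tree.time(tree.parent(edge))
                if v < w_d:
                    copies[edge] += 1
                    events.append(Event(fam, edge, "D", None, rel))
                elif v < w_d + w_l:
                    copies[edge] -= 1
                    events.append(Event(fam, edge, "L", None, rel))
                elif v < w_d + w_l + w_t:
                    donors = [nid for nid in live
                              if nid != edge and copies[nid] > 0]
                    weights = np.array([copies[nid] for nid in donors], float)
                    donor = donors[
                        rng.choice(len(donors), p=weights / weights.sum())]
                    copies[edge] += 1
                    events.append(Event(fam, edge, "T", donor, rel))
                else:
                    copies[edge] += 1
                    events.append(Event(fam, edge, "O", None, rel))
        for nid, k in copies.items():  # edges ending at the final time
            if tree.is_tip(nid):
                counts[fi, tip_idx[nid]] = k

    matrix = PresenceMatrix(pd.DataFrame(counts, index=families, columns=tips))
    return matrix, EventLog(events, root_presence)


def replay_event_log(tree: SpeciesTree, log: EventLog) -> PresenceMatrix:
    """Re-derive tip copy counts by replaying an event log from the root.

    Independent of the simulator's internal state: only the root
    presence, the event records and the tree geometry are used.
    """
    tips = tree.tips
    tip_idx = {t: j for j, t in enumerate(tips)}
    families = sorted(log.root_presence)
    fam_idx = {f: i for i, f in enumerate(families)}
    counts = np.zeros((len(families), len(tips)), dtype=int)

    by_family: dict[str, list[tuple[float, Event]]] = {f: [] for f in families}
    for e in log.events:
        abs_time = tree.time(tree.parent(e.branch)) + e.time
        by_family.setdefault(e.family, []).append((abs_time, e))

    node_order = sorted(
        (nid for nid in tree.preorder() if tree.parent(nid) is not None),
        key=lambda nid: tree.time(nid),
    )
    for fam in families:
        fevents = by_family.get(fam, [])
        fevents.sort(key=lambda te: te[0])
        copies = {c: log.root_presence[fam] for c in tree.children(tree.root)}
        ei = 0
        for nid in node_order:
            tau = tree.time(nid)
            while ei < len(fevents) and fevents[ei][0] < tau:
                _, e = fevents[ei]
                delta = {"D": 1, "T": 1, "O": 1, "L": -1}[e.type]
                copies[e.branch] = copies.get(e.branch, 0) + delta
                ei += 1
            k = copies.pop(nid, 0)
            if tree.is_tip(nid):
                counts[fam_idx[fam], tip_idx[nid]] = k
            else:
                for c in tree.children(nid):
                    copies[c] = copies.get(c, 0) + k
        while ei < len(fevents):  # events after the last closing node: none expected
            _, e = fevents[ei]
            copies[e.branch] = copies.get(e.branch, 0) + (
                1 if e.type in ("D", "T", "O") else -1
            )
            ei += 1
    return PresenceMatrix(pd.DataFrame(counts, index=families, columns=tips))


def simulate_binary_gain_loss(tree: SpeciesTree, gain: float, loss: float,
                              root_prob: float, n_families: int,
                              seed: int) -> PresenceMatrix:
    """Sample presence/absence under the two-state gain/loss Markov chain.

    The per-branch transition probabilities are the exact two-state
    continuous-time Markov solution, so this generator matches the
    model fitted by :func:`dtlflux.ancestral.fit_gain_loss_model`
    (used for parameter-recovery checks).
    """
    if gain < 0 or loss < 0 or gain + loss <= 0:
        raise ValueError("need gain, loss >= 0 with gain + loss > 0")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(int(seed))
    s = gain + loss
    states: dict[str, np.ndarray] = {
        tree.root: (rng.random(n_families) < root_prob).astype(int)
    }
    for nid in tree.preorder():
        if nid == tree.root:
            continue
        t = tree.length(nid)
        decay = np.exp(-s * t)
        p1_from0 = gain / s * (1.0 - decay)
        p1_from1 = 1.0 - loss / s * (1.0 - decay)
        parent = states[tree.parent(nid)]
        p1 = np.where(parent == 1, p1_from1, p1_from0)
        states[nid] = (rng.random(n_families) < p1).astype(int)
    tips = tree.tips
    width = max(4, len(str(n_families)))
    families = [f"fam{i + 1:0{width}d}" for i in range(n_families)]
    data = np.column_stack([states[t] for t in tips])
    return PresenceMatrix(pd.DataFrame(data, index=families, columns=tips))


# ---------------------------------------------------------------------------
# proteomes with a planted OGT signal
# ---------------------------------------------------------------------------

def assign_tip_ogts(tree: SpeciesTree, low: float, high: float, seed: int,
                    clade_offsets: Optional[Mapping[str, float]] = None
                    ) -> dict[str, float]:
    """Assign uniform OGTs to tips, with optional per-clade offsets.

    Offsets model lineages shifted toward hotter (positive) or cooler
    habitats; values are clipped to [0, 110] degC.
    """
    rng = np.random.default_rng(int(seed))
    out = {}
    for tid in tree.tips:
        ogt = rng.uniform(low, high)
        clade = tree.node(tid).clade
        if clade_offsets and clade in clade_offsets:
            ogt += clade_offsets[clade]
        out[tid] = float(np.clip(ogt, 0.0, 110.0))
    return out


def simulate_proteomes(tree: SpeciesTree, ogt_by_tip: Mapping[str, float],
                       slope: float, baseline_freqs: Optional[Mapping[str, float]] = None,
                       n_residues: int = 200_000, seed: int = 0,
                       mean_protein_length: int = 300) -> SyntheticProteomeSet:
    """Sample proteomes whose IVYWREL content tracks OGT linearly.

    For genome g the expected IVYWREL fraction is
    ``f0 + slope * (OGT_g - mean OGT)`` (clipped to (0, 1)), where f0 is
    the baseline IVYWREL mass; residues are drawn i.i.d. (multinomial
    with ``n_residues`` draws) after scaling the within-class baseline
    frequencies, then chopped into protein-sized sequences.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    freqs = dict(baseline_freqs) if baseline_freqs is not None else dict(BASELINE_AA_FREQS)
    if set(freqs) != set(BASELINE_AA_FREQS):
        raise ValueError("baseline frequencies must cover the 20 canonical amino acids")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"baseline frequencies sum to {total}, expected 1")
    for tid, ogt in ogt_by_tip.items():
        if not 0.0 <= ogt <= 110.0:
            raise ValueError(f"OGT of {tid!r} outside [0, 110] degC")
    missing = [t for t in tree.tips if t not in ogt_by_tip]
    if missing:
        raise ValueError(f"no OGT for tips: {missing[:5]}")

    rng = np.random.default_rng(int(seed))
    letters = sorted(freqs)
    base = np.array([freqs[a] for a in letters])
    in_set = np.array([a in IVYWREL for a in letters])
    f0 = float(base[in_set].sum())
    mean_ogt = float(np.mean([ogt_by_tip[t] for t in tree.tips]))

    sequences: dict[str, list[str]] = {}
    eps = 1e-3
    for tid in tree.tips:
        target = float(np.clip(f0 + slope * (ogt_by_tip[tid] - mean_ogt),
                               eps, 1.0 - eps))
        p = base.copy()
        p[in_set] *= target / f0
        p[~in_set] *= (1.0 - target) / (1.0 - f0)
        p /= p.sum()
        residues = rng.choice(letters, size=n_residues, p=p)
        seqs = [
            "".join(residues[i:i + mean_protein_length])
            for i in range(0, n_residues, mean_protein_length)
        ]
        sequences[tid] = seqs
    return SyntheticProteomeSet(
        sequences=sequences,
        true_ogt={t: float(ogt_by_tip[t]) for t in tree.tips},
        baseline_freqs=freqs,
        slope=float(slope),
    )


def simulate_pathway_groupings(families: Sequence[str],
                               genes_per_category: int = 8,
                               alternative_fraction: float = 0.2,
                               seed: int = 0):
    """Group the leading synthetic families into pFLAG-like pathways.

    Builds one pathway per canonical pFLAG category from consecutive
    family ids, occasionally merging two families into one step as
    isofunctional alternatives.  Deterministic for a fixed seed.
    Returns a list of :class:`dtlflux.pathways.PathwayDef`.
    """
    from .pathways import CATEGORY_ORDER, PathwayDef

    needed = genes_per_category * len(CATEGORY_ORDER)
    if len(families) < needed:
        raise ValueError(
            f"need >= {needed} families for {len(CATEGORY_ORDER)} categories "
            f"of {genes_per_category} genes; got {len(families)}")
    rng = np.random.default_rng(int(seed))
    defs = []
    cursor = 0
    for ci, category in enumerate(CATEGORY_ORDER):
        members = list(families[cursor:cursor + genes_per_category])
        cursor += genes_per_category
        steps: list[frozenset[str]] = []
        i = 0
        while i < len(members):
            if i + 1 < len(members) and rng.random() < alternative_fraction:
                steps.append(frozenset(members[i:i + 2]))
                i += 2
            else:
                steps.append(frozenset([members[i]]))
                i += 1
        defs.append(PathwayDef(
            pathway_id=f"pw{ci + 1}_{category.split()[0].replace('-', '_')}",
            name=f"synthetic {category} pathway",
            category=category,
            steps=tuple(steps),
        ))
    return defs


# ---------------------------------------------------------------------------
# gene-coordinate annotations
# ---------------------------------------------------------------------------

def simulate_annotation(genome_length: int, n_genes: int,
                        target_overlap_fraction: float, gc: float, seed: int,
                        genome_id: str = "genome", mean_gene_length: int = 800,
                        ) -> SyntheticAnnotation:
    """Lay out gene intervals with a controlled overlapping-gene fraction.

    Genes are placed left to right on a single contig; a target fraction
    of them is arranged into overlapping pairs (1-60 bp shared).  The
    realised overlap fraction is exact up to pairing granularity (within
    1/n_genes of the target).  Raises
    :class:`InfeasibleConfigurationError` when the requested genes
    cannot fit into the genome.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if not 0.0 <= target_overlap_fraction <= 1.0:
        raise ValueError("target_overlap_fraction must be in [0, 1]")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    contig = f"{genome_id}_c1"
    if n_genes == 0:
        return SyntheticAnnotation(genome_id, contig, int(genome_length), gc, [])

    rng = np.random.default_rng(int(seed))
    shape = 8.0
    lengths = np.maximum(
        90, rng.gamma(shape, mean_gene_length / shape, size=n_genes).astype(int)
    )
    n_overlapping = round(target_overlap_fraction * n_genes)
    n_pairs = n_overlapping // 2
    # which genes start an overlapping pair: evenly spread, deterministic
    pair_starts = set()
    if n_pairs:
        stride = n_genes / n_pairs
        pair_starts = {min(int(i * stride), n_genes - 2) for i in range(n_pairs)}
        while len(pair_starts) < n_pairs:  # collisions at small strides
            for i in range(n_genes - 1):
                if i not in pair_starts and (i + 1) not in pair_starts \
                        and (i - 1) not in pair_starts:
                    pair_starts.add(i)
                    break
            else:
                break

    overlaps = np.zeros(n_genes, dtype=int)  # overlap of gene i with gene i-1
    for i in sorted(pair_starts):
        cap = int(min(60, lengths[i] - 1, lengths[i + 1] - 1))
        overlaps[i + 1] = rng.integers(1, cap + 1)
    span = int(lengths.sum() - overlaps.sum())
    slack = int(genome_length) - span
    if slack < 0:
        raise InfeasibleConfigurationError(
            f"{n_genes} genes spanning {span} bp cannot fit into "
            f"{genome_length} bp"
        )
    gaps = rng.multinomial(slack, np.full(n_genes, 1.0 / n_genes))
    # overlapping pairs must stay contiguous: move their internal gap out
    for i in range(1, n_genes):
        if overlaps[i] > 0 and gaps[i] > 0:
            gaps[i - 1] += gaps[i]
            gaps[i] = 0

    genes: list[GeneRecord] = []
    pos = 0
    for i in range(n_genes):
        start = pos + int(gaps[i]) - int(overlaps[i])
        end = start + int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(contig, start, end, strand))
        pos = end
    assert pos <= genome_length
    return SyntheticAnnotation(genome_id, contig, int(genome_length), gc, genes)
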