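"""Ancestral gene-content reconstruction from phylogenetic profiles.

Two reconstruction routes are provided:

* **Asymmetric Wagner parsimony** (Sankoff dynamic programming) with
  separate gain and loss penalties, deterministic absent-preferring
  tie-breaking resolved root-ward.
* A **two-state continuous-time Markov model** (gain rate mu for 0->1,
  loss rate lambda for 1->0, root presence prior pi) fitted by maximum
  likelihood via Felsenstein pruning, with marginal ancestral
  posteriors from the standard up-down algorithm.

Both operate on presence/absence profiles only.  They are a
profile-level stand-in for gene-tree-aware reconciliation: duplications
are invisible to profiles (D is always 0 here) and the origination /
transfer split of gains is a stated deterministic rule, flagged in the
outputs as profile-approximated.  Externally computed reconciliation
event tables (e.g. ALE output) can be ingested instead via
:func:`ingest_event_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .matrix import PresenceMatrix
from .simulate import Event
from .tree import SpeciesTree

__all__ = [
    "GainLossModel",
    "BranchEventTally",
    "ReconciliationMismatchError",
    "filter_families",
    "sankoff_parsimony",
    "fit_gain_loss_model",
    "marginal_ancestral_posterior",
    "reconstruct_ancestral_states",
    "extract_branch_events",
    "ingest_event_table",
]

EVENT_COLUMNS = ["D", "T", "L", "O"]


class ReconciliationMismatchError(ValueError):
    """Event-table node labels do not match the species tree."""


@dataclass(frozen=True)
class GainLossModel:
    """Two-state gain/loss Markov model of one gene family's presence."""

    gain: float
    loss: float
    root_prior: float

    def __post_init__(self):
        if self.gain < 0 or self.loss < 0:
            raise ValueError("rates must be >= 0")
        if self.gain + self.loss <= 0:
            raise ValueError("gain + loss must be > 0 for identifiability")
        if not 0.0 <= self.root_prior <= 1.0:
            raise ValueError("root prior must be in [0, 1]")

    def transition_matrix(self, t: float) -> np.ndarray:
        """P[i, j] = P(state j at branch end | state i at branch start)."""
        s = self.gain + self.loss
        decay = np.exp(-s * t)
        p01 = self.gain / s * (1.0 - decay)
        p10 = self.loss / s * (1.0 - decay)
        return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


class BranchEventTally:
    """Per-branch D/T/L/O event counts, optionally donor-resolved.

    Wraps a DataFrame indexed by branch (node) id with columns D, T, L,
    O.  ``transfer_records`` keeps (donor, recipient, family) triples
    when donors are known.
    """

    def __init__(self, counts: pd.DataFrame,
                 transfer_records: Optional[list[tuple[str, str, str]]] = None):
        missing = [c for c in EVENT_COLUMNS if c not in counts.columns]
        if missing:
            raise ValueError(f"tally missing columns {missing}")
        if (counts[EVENT_COLUMNS].to_numpy() < 0).any():
            raise ValueError("event counts must be >= 0")
        self.counts = counts[EVENT_COLUMNS].copy()
        self.transfer_records = list(transfer_records or [])

    @classmethod
    def from_event_log(cls, tree: SpeciesTree, log) -> "BranchEventTally":
        """Tally a ground-truth event log over branches."""
        counts = pd.DataFrame(
            0, index=tree.node_ids(), columns=EVENT_COLUMNS, dtype=float
        )
        transfers = []
        for e in log:
            counts.loc[e.branch, e.type] += 1
            if e.type == "T":
                transfers.append((e.donor, e.branch, e.family))
        return cls(counts, transfers)

    @property
    def branches(self) -> list[str]:
        return list(self.counts.index)

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset(self, branches) -> "BranchEventTally":
        sub = self.counts.loc[list(branches)]
        keep = set(branches)
        recs = [r for r in self.transfer_records if r[1] in keep]
        return BranchEventTally(sub, recs)

    def __repr__(self) -> str:  # pragma: no cover
        tot = self.totals()
        return ("BranchEventTally(" +
                ", ".join(f"{c}={tot[c]:g}" for c in EVENT_COLUMNS) + ")")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_families(matrix: PresenceMatrix, min_members: int) -> PresenceMatrix:
    """Drop families with fewer than ``min_members`` members in total.

    Members are gene copies summed over genomes when copy counts are
    available (a family with counts 3+2 in two genomes has 5 members);
    with a plain binary matrix this reduces to the number of genomes
    carrying the family.  Row order is preserved.
    """
    if min_members < 1:
        raise ValueError("min_members must be >= 1")
    keep = matrix.member_counts() >= min_members
    return PresenceMatrix(matrix.counts.loc[keep])


# ---------------------------------------------------------------------------
# Sankoff parsimony
# ---------------------------------------------------------------------------

def sankoff_parsimony(tree: SpeciesTree, profile: dict[str, int],
                      gain_penalty: float = 2.0, loss_penalty: float = 1.0,
                      ) -> tuple[dict[str, int], float]:
    """Minimum-cost ancestral presence/absence under asymmetric penalties.

    Cost of a full labelling is ``gain_penalty * #(0->1 edges) +
    loss_penalty * #(1->0 edges)``.  Ties are broken by preferring
    absence (state 0), resolved root-ward: the root picks the cheaper
    state (0 on ties), then each child conditions on its parent's
    choice.  Returns (states over all nodes, minimal cost).
    """
    if gain_penalty <= 0 or loss_penalty <= 0:
        raise ValueError("penalties must be > 0")
    missing = [t for t in tree.tips if t not in profile]
    if missing:
        raise ValueError(f"profile missing tips: {missing[:5]}")
    INF = float("inf")
    trans = np.array([[0.0, gain_penalty], [loss_penalty, 0.0]])
    cost: dict[str, np.ndarray] = {}
    for nid in tree.postorder():
        if tree.is_tip(nid):
            state = int(profile[nid])
            if state not in (0, 1):
                raise ValueError(f"tip state of {nid!r} must be 0 or 1")
            c = np.array([INF, INF])
            c[state] = 0.0
        else:
            c = np.zeros(2)
            for child in tree.children(nid):
                cc = cost[child]
                for s in (0, 1):
                    c[s] += min(cc[0] + trans[s, 0], cc[1] + trans[s, 1])
        cost[nid] = c
    states: dict[str, int] = {}
    root_cost = cost[tree.root]
    min_cost = float(min(root_cost))
    states[tree.root] = 0 if root_cost[0] <= root_cost[1] else 1
    for nid in tree.preorder():
        if nid == tree.root:
            continue
        p = states[tree.parent(nid)]
        c = cost[nid]
        choice0 = c[0] + trans[p, 0]
        choice1 = c[1] + trans[p, 1]
        states[nid] = 0 if choice0 <= choice1 else 1
    return states, min_cost


# ---------------------------------------------------------------------------
# two-state Markov model: likelihood, fitting, posteriors
# ---------------------------------------------------------------------------

def _partials(tree: SpeciesTree, binary: np.ndarray, tip_order: list[str],
              model: GainLossModel) -> dict[str, np.ndarray]:
    """Felsenstein pruning partial likelihoods, vectorised over families.

    ``binary``: families x tips array in ``tip_order``.  Returns node id
    -> (n_families, 2) conditional likelihoods of the subtree below.
    """
    tip_idx = {t: j for j, t in enumerate(tip_order)}
    partial: dict[str, np.ndarray] = {}
    n_fam = binary.shape[0]
    for nid in tree.postorder():
        if tree.is_tip(nid):
            obs = binary[:, tip_idx[nid]]
            arr = np.zeros((n_fam, 2))
            arr[np.arange(n_fam), obs] = 1.0
        else:
            arr = np.ones((n_fam, 2))
            for child in tree.children(nid):
                P = model.transition_matrix(tree.length(child))
                arr *= partial[child] @ P.T
        partial[nid] = arr
    return partial


def profile_log_likelihood(tree: SpeciesTree, matrix: PresenceMatrix,
                           model: GainLossModel) -> float:
    """Total log-likelihood of all family profiles under the model."""
    matrix.check_against_tree(tree)
    tips = tree.tips
    binary = matrix.binary[tips].to_numpy()
    partial = _partials(tree, binary, tips, model)
    prior = np.array([1.0 - model.root_prior, model.root_prior])
    lik = partial[tree.root] @ prior
    if (lik <= 0).any():
        return -np.inf
    return float(np.log(lik).sum())


_GRID_RATES = (0.02, 0.2, 1.0)
_GRID_PRIORS = (0.2, 0.8)
_RATE_BOUNDS = (1e-6, 50.0)


def fit_gain_loss_model(tree: SpeciesTree, matrix: PresenceMatrix,
                        ) -> GainLossModel:
    """Maximum-likelihood (mu, lambda, pi) for the gain/loss model.

    Deterministic: L-BFGS-B on (log mu, log lambda, logit pi) from a
    fixed grid of starts; the best converged optimum wins (ties go to
    the earlier grid point).  All-present or all-absent matrices pin pi
    at the corresponding boundary and leave rates at the search bounds.
    """
    if matrix.shape[0] < 10:
        raise ValueError("need >= 10 families to fit the model")
    if tree.total_length <= 0:
        raise ValueError("tree must have positive total length")
    matrix.check_against_tree(tree)

    binary = matrix.binary.to_numpy()
    if binary.all() or not binary.any():
        import warnings
        all_present = bool(binary.all())
        warnings.warn(
            "degenerate matrix (all families %s everywhere): root prior "
            "pinned, rates at search bounds"
            % ("present" if all_present else "absent"), UserWarning)
        lo = _RATE_BOUNDS[0]
        return GainLossModel(gain=lo, loss=lo,
                             root_prior=1.0 if all_present else 0.0)

    def objective(theta: np.ndarray) -> float:
        mu, lam = np.exp(theta[0]), np.exp(theta[1])
        pi = 1.0 / (1.0 + np.exp(-theta[2]))
        model = GainLossModel(mu, lam, pi)
        val = -profile_log_likelihood(tree, matrix, model)
        # keep the objective finite so numeric gradients stay defined
        return min(val, 1e12)

    log_bounds = (np.log(_RATE_BOUNDS[0]), np.log(_RATE_BOUNDS[1]))
    bounds = [log_bounds, log_bounds, (-12.0, 12.0)]
    best = None
    for mu0 in _GRID_RATES:
        for lam0 in _GRID_RATES:
            for pi0 in _GRID_PRIORS:
                x0 = np.array([np.log(mu0), np.log(lam0),
                               np.log(pi0 / (1.0 - pi0))])
                res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
                if best is None or res.fun < best.fun - 1e-12:
                    best = res
    mu, lam = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    pi = float(1.0 / (1.0 + np.exp(-best.x[2])))
    return GainLossModel(gain=mu, loss=lam, root_prior=pi)


def marginal_ancestral_posterior(tree: SpeciesTree, profile: dict[str, int],
                                 model: GainLossModel) -> dict[str, float]:
    """Per-node posterior presence probability via the up-down algorithm.

    Tips have posterior equal to their observed state (observation is
    error-free).  Internal-node posteriors combine the inside (pruning)
    likelihood with the outside likelihood propagated from the root
    prior.
    """
    for rate in (model.gain, model.loss):
        if not np.isfinite(rate):
            raise ValueError("model rates must be finite")
    tips = tree.tips
    missing = [t for t in tips if t not in profile]
    if missing:
        raise ValueError(f"profile missing tips: {missing[:5]}")
    binary = np.array([[int(profile[t]) for t in tips]])
    inside = _partials(tree, binary, tips, model)
    prior = np.array([1.0 - model.root_prior, model.root_prior])
    outside: dict[str, np.ndarray] = {tree.root: prior.copy()}
    for nid in tree.preorder():
        if tree.is_tip(nid):
            continue
        children = tree.children(nid)
        for child in children:
            sib_term = np.ones(2)
            for sib in children:
                if sib is child:
                    continue
                P_sib = model.transition_matrix(tree.length(sib))
                sib_term *= (inside[sib][0] @ P_sib.T)
            P = model.transition_matrix(tree.length(child))
            outside[child] = (outside[nid] * sib_term) @ P
    posterior: dict[str, float] = {}
    for nid in tree.preorder():
        if tree.is_tip(nid):
            posterior[nid] = float(profile[nid])
            continue
        joint = outside[nid] * inside[nid][0]
        total = joint.sum()
        if total <= 0:
            raise ValueError("zero-probability profile under the model")
        posterior[nid] = float(joint[1] / total)
    return posterior


def reconstruct_ancestral_states(tree: SpeciesTree, matrix: PresenceMatrix,
                                 method: str = "parsimony",
                                 gain_penalty: float = 2.0,
                                 loss_penalty: float = 1.0,
                                 model: Optional[GainLossModel] = None,
                                 ) -> pd.DataFrame:
    """Ancestral states for every family: node x family DataFrame.

    ``method='parsimony'`` gives binary states; ``method='markov'``
    gives posterior presence probabilities (fitting the model first if
    none is supplied).
    """
    matrix.check_against_tree(tree)
    binary = matrix.binary
    nodes = tree.node_ids()
    out = pd.DataFrame(index=nodes, columns=binary.index, dtype=float)
    if method == "parsimony":
        for fam in binary.index:
            profile = {t: int(binary.loc[fam, t]) for t in tree.tips}
            states, _ = sankoff_parsimony(tree, profile, gain_penalty, loss_penalty)
            out[fam] = pd.Series(states)
    elif method == "markov":
        if model is None:
            model = fit_gain_loss_model(tree, matrix)
        for fam in binary.index:
            profile = {t: int(binary.loc[fam, t]) for t in tree.tips}
            post = marginal_ancestral_posterior(tree, profile, model)
            out[fam] = pd.Series(post)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


# ---------------------------------------------------------------------------
# event extraction from ancestral states
# ---------------------------------------------------------------------------

def extract_branch_events(states: pd.DataFrame, tree: SpeciesTree,
                          threshold: Optional[float] = None,
                          ) -> tuple[BranchEventTally, list[Event]]:
    """Turn binary ancestral states into per-branch gain/loss events.

    Per family: an edge with parent absent and child present is a gain,
    parent present and child absent a loss.  The first gain in preorder
    is labelled an origination; every later gain of the same family is
    labelled a transfer whose donor is recorded as the earliest lineage
    already carrying the family (the preorder-first gain branch, or the
    root for families ancestrally present).  Presence at the root is
    ancestral state, not an event, so a family present everywhere
    produces zero events.  This origination/transfer split is a
    deterministic convention, not a mechanistic inference: profiles
    cannot distinguish the two, and duplications are invisible (D is
    always 0).

    Probabilistic states must be binarised: pass ``threshold`` (e.g.
    0.5).  Presence requires probability strictly greater than the
    threshold, so a tie at the threshold resolves to absent, consistent
    with the absent-preferring parsimony tie rule.
    """
    arr = states.to_numpy(dtype=float)
    is_binary = np.isin(arr[~np.isnan(arr)], (0.0, 1.0)).all()
    if not is_binary:
        if threshold is None:
            raise ValueError(
                "states are not binary; pass threshold= to binarise posteriors"
            )
        states = (states > threshold).astype(int)
    else:
        states = states.astype(int)
    missing = [n for n in tree.node_ids() if n not in states.index]
    if missing:
        raise ValueError(f"states missing nodes: {missing[:5]}")

    counts = pd.DataFrame(0, index=tree.node_ids(), columns=EVENT_COLUMNS,
                          dtype=float)
    events: list[Event] = []
    preorder = tree.node_ids()
    root = tree.root
    for fam in states.columns:
        col = states[fam]
        # ancestral presence at the root seeds the donor pool without
        # counting as an event
        first_presence: Optional[str] = root if int(col[root]) == 1 else None
        for nid in preorder:
            if nid == root:
                continue
            child_state = int(col[nid])
            parent_state = int(col[tree.parent(nid)])
            if parent_state == 0 and child_state == 1:
                if first_presence is None:
                    first_presence = nid
                    counts.loc[nid, "O"] += 1
                    events.append(Event(fam, nid, "O", None, 0.0))
                else:
                    counts.loc[nid, "T"] += 1
                    events.append(Event(fam, nid, "T", first_presence, 0.0))
            elif parent_state == 1 and child_state == 0:
                counts.loc[nid, "L"] += 1
                events.append(Event(fam, nid, "L", None, 0.0))
    transfers = [(e.donor, e.branch, e.family) for e in events if e.type == "T"]
    return BranchEventTally(counts, transfers), events


# ---------------------------------------------------------------------------
# ingestion of external reconciliation tables
# ---------------------------------------------------------------------------

def ingest_event_table(path, tree: Optional[SpeciesTree] = None,
                       ) -> tuple[BranchEventTally, pd.DataFrame]:
    """Read an ALE-style per-family reconciliation event table.

    Expected columns: ``node``, ``family``, ``D``, ``T``, ``L``, ``O``
    (reals allowed — reconciliation frequencies are expected counts) and
    optionally ``donor``.  Frequencies are summed per branch; the
    returned DataFrame reports each category both raw and rounded
    (half-to-even).  When a tree is given, node labels are validated
    against it and unknown labels raise
    :class:`ReconciliationMismatchError`.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"node": str})
    required = ["node", "family"] + EVENT_COLUMNS
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    vals = table[EVENT_COLUMNS].to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative event counts in table")
    if tree is not None:
        unknown = sorted(set(table["node"]) - set(tree.node_ids()))
        if unknown:
            raise ReconciliationMismatchError(
                f"node labels absent from the species tree: {unknown}"
            )
    raw = table.groupby("node")[EVENT_COLUMNS].sum()
    if tree is not None:
        raw = raw.reindex(tree.node_ids(), fill_value=0.0)
    report = raw.copy()
    for c in EVENT_COLUMNS:
        report[f"{c}_rounded"] = np.round(raw[c]).astype(int)  # half-to-even
    transfers = []
    if "donor" in table.columns:
        tmask = (table["T"].to_numpy(dtype=float) > 0) & table["donor"].notna()
        for _, row in table[tmask].iterrows():
            transfers.append((str(row["donor"]), str(row["node"]),
                              str(row["family"])))
    tally = BranchEventTally(raw, transfers)
    return tally, report
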