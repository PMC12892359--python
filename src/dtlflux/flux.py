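"""Per-node evolutionary event-flux summaries.

Aggregates duplication/transfer/loss/origination tallies into the
quantities used to read evolutionary regime off a reconciliation:
category totals and percentage shares, the log10 gain/loss ratio per
node (loss-dominated nodes are negative — reductive evolution; gain
dominated nodes positive — HGT-driven expansion), ranked HGT hotspots,
and a donor-clade x recipient-clade transfer matrix from which putative
symbiont-host pairings are conjectured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .ancestral import EVENT_COLUMNS, BranchEventTally

__all__ = [
    "FluxSummary",
    "flux_summary",
    "gain_loss_log_ratio",
    "hgt_hotspots",
    "transfer_partner_summary",
    "gain_loss_table",
]

GAINS_DEFAULT = frozenset({"D", "T", "O"})


@dataclass(frozen=True)
class FluxSummary:
    """Totals and percentage shares of event categories over a node set.

    ``percentages`` are rounded half-to-even to 2 decimals;
    ``raw_percentages`` keep full precision.  When the total is zero
    the shares are undefined (None), not zero.
    """

    counts: dict[str, float]
    total: float
    raw_percentages: dict[str, Optional[float]]
    percentages: dict[str, Optional[float]]
    n_nodes: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, self.counts[c], self.raw_percentages[c], self.percentages[c])
            for c in EVENT_COLUMNS
        ]
        return pd.DataFrame(
            rows, columns=["category", "count", "raw_percentage", "percentage"]
        )


def flux_summary(tallies: BranchEventTally,
                 node_set: Optional[Sequence[str]] = None) -> FluxSummary:
    """Sum D/T/L/O over a node set and express each as a share of total."""
    if tallies.counts.empty:
        raise ValueError("empty tally")
    counts = tallies.counts
    if node_set is not None:
        counts = counts.loc[list(node_set)]
    sums = counts[EVENT_COLUMNS].sum(axis=0)
    total = float(sums.sum())
    if total > 0:
        raw = {c: 100.0 * float(sums[c]) / total for c in EVENT_COLUMNS}
        rounded = {c: round(raw[c], 2) for c in EVENT_COLUMNS}  # half-to-even
    else:
        raw = {c: None for c in EVENT_COLUMNS}
        rounded = dict(raw)
    return FluxSummary(
        counts={c: float(sums[c]) for c in EVENT_COLUMNS},
        total=total,
        raw_percentages=raw,
        percentages=rounded,
        n_nodes=len(counts),
    )


def gain_loss_log_ratio(node_counts: Mapping[str, float],
                        gains_definition: frozenset = GAINS_DEFAULT,
                        pseudocount: float = 1.0) -> float:
    """log10 of (gains / losses) at one node.

    ``gains_definition`` selects which of D, T, O count as gains
    (default: all content-increasing events).  The pseudocount is
    applied to both numerator and denominator, and only when one side
    is zero, so it never perturbs typical nodes.
    """
    bad = set(gains_definition) - {"D", "T", "O"}
    if bad:
        raise ValueError(f"gains_definition may only contain D, T, O; got {bad}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    gains = sum(float(node_counts.get(c, 0.0)) for c in sorted(gains_definition))
    losses = float(node_counts.get("L", 0.0))
    if gains < 0 or losses < 0:
        raise ValueError("negative event counts")
    if gains == 0 or losses == 0:
        if pseudocount == 0:
            raise ValueError(
                "zero gains or losses with pseudocount 0: ratio undefined")
        gains += pseudocount
        losses += pseudocount
    return math.log10(gains / losses)


def gain_loss_table(tallies: BranchEventTally,
                    gains_definition: frozenset = GAINS_DEFAULT,
                    pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-node gain, loss and log10 gain/loss ratio table."""
    rows = []
    for nid, row in tallies.counts.iterrows():
        gains = sum(float(row[c]) for c in sorted(gains_definition))
        losses = float(row["L"])
        if gains == 0 and losses == 0:
            ratio = float("nan")
        else:
            ratio = gain_loss_log_ratio(row.to_dict(), gains_definition,
                                        pseudocount)
        rows.append((nid, gains, losses, ratio))
    return pd.DataFrame(rows, columns=["node", "gains", "losses",
                                       "log10_gain_loss"])


def hgt_hotspots(tallies: BranchEventTally, k: int = 50) -> pd.DataFrame:
    """The k nodes with the most transfer events.

    A pure sort: descending by T count, ties broken by node id in
    lexicographic (string) ascending order.  Returns min(k, #nodes)
    rows with columns node, T.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    items = sorted(
        ((nid, float(t)) for nid, t in tallies.counts["T"].items()),
        key=lambda it: (-it[1], it[0]),
    )
    return pd.DataFrame(items[:k], columns=["node", "T"])


def transfer_partner_summary(transfer_records: Sequence[tuple[str, str, str]],
                             clade_map: Mapping[str, str]) -> pd.DataFrame:
    """Donor clade x recipient clade transfer-count matrix.

    ``transfer_records`` are (donor branch, recipient branch, family)
    triples; every branch must map to a clade.  The diagonal holds
    within-clade transfers.  Row/column marginals are appended as
    ``_total``.
    """
    unmapped = sorted(
        {b for rec in transfer_records for b in rec[:2] if b not in clade_map}
    )
    if unmapped:
        raise KeyError(f"branches without a clade mapping: {unmapped}")
    clades = sorted(set(clade_map.values()))
    mat = pd.DataFrame(0, index=clades, columns=clades, dtype=int)
    for donor, recipient, _fam in transfer_records:
        mat.loc[clade_map[donor], clade_map[recipient]] += 1
    mat["_total"] = mat.sum(axis=1)
    mat.loc["_total"] = mat.sum(axis=0)
    mat.index.name = "donor"
    mat.columns.name = "recipient"
    return mat
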