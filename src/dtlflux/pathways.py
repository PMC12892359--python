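"""Pathway completeness and pFLAG occurrence profiling.

pFLAGs ("putative free-living associated genes") are the gene families
of central metabolism and de novo biosynthesis — glycolysis, the TCA
cycle, nucleotide, amino-acid, cofactor and membrane biosynthesis —
that free-living prokaryotes almost always carry but host-dependent
symbionts frequently lack.  Profiling their presence per lineage, and
their completeness at ancestral nodes, is how host-dependency
transitions are read off a gene-content reconstruction.

Completeness is scored in two modes: *gene* mode (fraction of the
pathway's listed genes present — the default) and *step* mode (fraction
of reaction steps with at least one alternative enzyme present, so
isofunctional alternatives like pfkA/pfkC count once).  With posterior
presence probabilities, completeness is reported in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .matrix import PresenceMatrix
from .tree import SpeciesTree

__all__ = [
    "PathwayDef",
    "OccurrenceClass",
    "CATEGORY_ORDER",
    "pathway_completeness",
    "clade_occurrence",
    "classify_occurrence",
    "pflag_profile",
    "ancestral_completeness_trajectory",
    "load_pathway_definitions",
    "default_pflag_definitions",
]

# canonical pFLAG category display order
CATEGORY_ORDER = (
    "glycolysis",
    "TCA",
    "nucleotide biosynthesis",
    "amino-acid biosynthesis",
    "cofactor biosynthesis",
    "membrane biosynthesis",
)


@dataclass(frozen=True)
class PathwayDef:
    """A pathway: ordered steps, each a set of alternative gene families."""

    pathway_id: str
    name: str
    category: str
    steps: tuple[frozenset[str], ...]

    def __post_init__(self):
        if not self.steps:
            raise ValueError(f"pathway {self.pathway_id!r} has no steps")
        seen = set()
        for step in self.steps:
            if not step or any(not f for f in step):
                raise ValueError(
                    f"pathway {self.pathway_id!r}: empty step or family id")
            if step in seen:
                raise ValueError(
                    f"pathway {self.pathway_id!r}: duplicate step {set(step)}")
            seen.add(step)

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for step in self.steps:
            for g in sorted(step):
                if g not in out:
                    out.append(g)
        return out


@dataclass(frozen=True)
class OccurrenceClass:
    """Occurrence ratio of a gene in a clade, with its presence class.

    majority: ratio >= 0.5 (the boundary is inclusive); minority:
    0 < ratio < 0.5; absent: ratio == 0.
    """

    value: str
    ratio: float

    def __post_init__(self):
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError("ratio must be in [0, 1]")
        expected = classify_ratio(self.ratio)
        if self.value != expected:
            raise ValueError(
                f"class {self.value!r} inconsistent with ratio {self.ratio}")


def classify_ratio(ratio: float) -> str:
    if ratio == 0:
        return "absent"
    return "majority" if ratio >= 0.5 else "minority"


Content = Union[set, frozenset, Mapping[str, float]]


def pathway_completeness(content: Content, pathway: PathwayDef,
                         mode: str = "gene") -> float:
    """Fraction of a pathway present in a gene-content set.

    ``content`` is either a set of family ids or a mapping family ->
    posterior presence probability (expected completeness).  Gene mode
    averages presence over the pathway's listed genes; step mode over
    steps, a step being present when at least one alternative is (in
    expectation: 1 - prod(1 - p_alt)).
    """
    if mode not in ("gene", "step"):
        raise ValueError(f"unknown mode {mode!r}")
    probabilistic = isinstance(content, Mapping)

    def prob(gene: str) -> float:
        if probabilistic:
            p = float(content.get(gene, 0.0))
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"posterior of {gene!r} outside [0, 1]")
            return p
        return 1.0 if gene in content else 0.0

    if mode == "gene":
        genes = pathway.genes
        return sum(prob(g) for g in genes) / len(genes)
    total = 0.0
    for step in pathway.steps:
        miss = 1.0
        for g in step:
            miss *= 1.0 - prob(g)
        total += 1.0 - miss
    return total / len(pathway.steps)


def clade_occurrence(matrix: PresenceMatrix, clade_members: Sequence[str],
                     family: str) -> OccurrenceClass:
    """Occurrence ratio and class of one family over a clade's genomes."""
    if not clade_members:
        raise ValueError("clade_members must be nonempty")
    unknown = [g for g in clade_members if g not in matrix.counts.columns]
    if unknown:
        raise KeyError(f"unknown genome ids: {unknown}")
    if family not in matrix.counts.index:
        ratio = 0.0
    else:
        row = matrix.binary.loc[family, list(clade_members)]
        ratio = float(row.sum()) / len(clade_members)
    return OccurrenceClass(value=classify_ratio(ratio), ratio=ratio)


# backwards-friendly alias used by the CLI
classify_occurrence = clade_occurrence


def pflag_profile(matrix: PresenceMatrix,
                  clades: Mapping[str, Sequence[str]],
                  pflag_sets: Mapping[str, Sequence[str]],
                  allow_overlap: bool = False) -> pd.DataFrame:
    """Occurrence table: one row per (clade, category, family).

    ``pflag_sets`` maps a category to its family ids; categories are
    emitted in canonical pFLAG order (unknown categories after, in
    input order).  Families missing from the matrix are reported as
    absent with a provenance note rather than raising.  Overlapping
    clades are rejected unless ``allow_overlap`` is set, because
    occurrence ratios are per-lineage statistics.
    """
    if not allow_overlap:
        seen: dict[str, str] = {}
        for clade, members in clades.items():
            for g in members:
                if g in seen:
                    raise ValueError(
                        f"genome {g!r} in clades {seen[g]!r} and {clade!r}; "
                        "pass allow_overlap=True to permit this")
                seen[g] = clade
    cat_rank = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    categories = sorted(
        pflag_sets, key=lambda c: (cat_rank.get(c, len(cat_rank)),
                                   list(pflag_sets).index(c)))
    rows = []
    known = set(matrix.counts.index)
    for clade, members in clades.items():
        for cat in categories:
            for fam in pflag_sets[cat]:
                if fam in known:
                    occ = clade_occurrence(matrix, list(members), fam)
                    note = ""
                else:
                    occ = OccurrenceClass("absent", 0.0)
                    note = "family not in matrix"
                rows.append((clade, cat, fam, occ.ratio, occ.value, note))
    return pd.DataFrame(
        rows, columns=["clade", "category", "family", "ratio", "class", "note"]
    )


def ancestral_completeness_trajectory(states: pd.DataFrame, tree: SpeciesTree,
                                      pathways: Sequence[PathwayDef],
                                      mode: str = "gene") -> pd.DataFrame:
    """Per-node, per-category pathway completeness over the whole tree.

    ``states``: node x family DataFrame (binary or posterior).  Tip rows
    reproduce extant completeness computed directly from the matrix when
    the states are tip-consistent.  Multiple pathways in one category
    are averaged gene-weighted in gene mode (pooled gene lists) and
    step-weighted in step mode.
    """
    missing = [n for n in tree.node_ids() if n not in states.index]
    if missing:
        raise ValueError(f"states missing nodes: {missing[:5]}")
    by_category: dict[str, list[PathwayDef]] = {}
    for p in pathways:
        by_category.setdefault(p.category, []).append(p)
    rows = []
    for nid in tree.node_ids():
        content = {fam: float(states.loc[nid, fam]) for fam in states.columns}
        for cat, defs in by_category.items():
            if mode == "gene":
                genes = [g for p in defs for g in p.genes]
                value = sum(content.get(g, 0.0) for g in genes) / len(genes)
            else:
                num = sum(
                    pathway_completeness(content, p, mode="step") * len(p.steps)
                    for p in defs)
                value = num / sum(len(p.steps) for p in defs)
            rows.append((nid, cat, value, tree.is_tip(nid)))
    out = pd.DataFrame(rows, columns=["node", "category", "completeness", "is_tip"])
    return out


# ---------------------------------------------------------------------------
# pathway-definition files
# ---------------------------------------------------------------------------

def load_pathway_definitions(source) -> list[PathwayDef]:
    """Read pathway definitions from a TSV.

    Columns: ``pathway_id``, ``name``, ``category``, ``step_index``,
    ``alternatives`` (comma-separated family ids).  The file is the
    contract: edit it to redefine pFLAG membership.
    """
    table = pd.read_csv(source, sep="\t", comment="#",
                        dtype={"pathway_id": str, "alternatives": str})
    required = ["pathway_id", "name", "category", "step_index", "alternatives"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"pathway table missing columns {missing}")
    defs = []
    for pid, grp in table.groupby("pathway_id", sort=False):
        grp = grp.sort_values("step_index")
        steps = tuple(
            frozenset(a.strip() for a in row.split(",") if a.strip())
            for row in grp["alternatives"]
        )
        defs.append(PathwayDef(
            pathway_id=str(pid),
            name=str(grp["name"].iloc[0]),
            category=str(grp["category"].iloc[0]),
            steps=steps,
        ))
    return defs


def default_pflag_definitions() -> list[PathwayDef]:
    """The pFLAG pathway definitions shipped with the package.

    Seeded with marker genes of the six pFLAG categories (EMP
    glycolysis, TCA cycle, de novo purine/pyrimidine, amino-acid,
    cofactor and archaeal membrane-lipid biosynthesis).  Intended to be
    replaced by a study-specific file for real data.
    """
    with resources.files("dtlflux.data").joinpath("pflag_pathways.tsv").open() as fh:
        return load_pathway_definitions(fh)
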