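"""Gene-tree classification of HGT candidates and transfer-event clustering.

A candidate survives screening only if its gene tree places the query inside
a well-supported clade of outgroup (prokaryotic/viral) sequences.  Walking
rootward from the query leaf, the smallest ancestor with bootstrap support
at or above ``support_min`` defines the decision clade C (minus the query):

* C entirely outgroup, ingroup leaves elsewhere in the tree -> ``HGT``
* C entirely outgroup, no ingroup leaf anywhere            -> ``HGT_NT``
  (a transfer with no closely related ingroup species sampled at all)
* C contains any ingroup leaf                              -> ``VERTICAL``
* no supported ancestor below the root                     -> ``UNRESOLVED``

Only HGT and HGT_NT calls count as confirmed transfers.  Confirmed genes
sharing a gene family and a donor group are then merged into one transfer
event; events restricted to a single recipient species are "species
specific", the rest are shared.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

from .taxonomy import GroupLabel, TaxonomyDB, classify_species, donor_group

log = logging.getLogger(__name__)

QUERY_PREFIX = "QUERY"


class Call(enum.Enum):
    HGT = "HGT"
    HGT_NT = "HGT_NT"
    VERTICAL = "VERTICAL"
    UNRESOLVED = "UNRESOLVED"


CONFIRMED_CALLS = {Call.HGT, Call.HGT_NT}


@dataclass
class PhyloCall:
    gene_id: str
    call: Call
    donor_label: str = ""
    support_at_decision: float = 0.0

    @property
    def confirmed(self) -> bool:
        return self.call in CONFIRMED_CALLS


@dataclass
class HgtEvent:
    event_id: str
    family_id: str
    donor_label: str
    recipient_species: set[str] = field(default_factory=set)
    gene_ids: list[str] = field(default_factory=list)

    @property
    def species_specific(self) -> bool:
        return len(self.recipient_species) == 1


class TreeStructureError(ValueError):
    pass


# --------------------------------------------------------------------- io

def load_gene_tree(path: str | Path) -> dendropy.Tree:
    """Parse a Newick gene tree; internal node labels hold support values."""
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def _leaf_label(leaf: dendropy.Node) -> str:
    return leaf.taxon.label if leaf.taxon is not None else (leaf.label or "")


def _query_leaf(tree: dendropy.Tree) -> dendropy.Node:
    queries = [
        lf for lf in tree.leaf_node_iter()
        if _leaf_label(lf).startswith(QUERY_PREFIX)
    ]
    if len(queries) != 1:
        raise TreeStructureError(
            f"expected exactly one {QUERY_PREFIX}-labelled leaf, found {len(queries)}"
        )
    return queries[0]


def _support(node: dendropy.Node) -> float:
    """Internal-node support from the Newick label; absent support is 0."""
    if node.label is None:
        return 0.0
    try:
        return float(node.label)
    except ValueError:
        return 0.0


# ----------------------------------------------------------------- rooting

def root_tree(
    tree: dendropy.Tree,
    taxonomy: TaxonomyDB | None = None,
    recipient: str | None = None,
) -> dendropy.Tree:
    """Root a gene tree deterministically.

    If a taxonomy is supplied and the tree contains leaves from a domain that
    is neither eukaryotic nor the dominant (candidate donor) non-eukaryote
    domain, the tree is rooted on that extraneous lineage; otherwise the
    tree is rooted at the midpoint of its longest leaf-to-leaf path.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise TreeStructureError("gene tree must have at least 3 leaves")

    if taxonomy is not None:
        domains: dict[str, list[dendropy.Node]] = {}
        for lf in leaves:
            lab = _leaf_label(lf)
            if lab.startswith(QUERY_PREFIX):
                continue
            try:
                dom = taxonomy.lineage(lab)[0]
            except KeyError:
                continue
            domains.setdefault(dom, []).append(lf)
        non_euk = {d: ls for d, ls in domains.items() if d != "Eukaryota"}
        if len(non_euk) > 1:
            donor_dom = max(non_euk, key=lambda d: (len(non_euk[d]), d))
            extraneous = sorted(
                (d for d in non_euk if d != donor_dom),
                key=lambda d: (len(non_euk[d]), d),
            )[0]
            node = non_euk[extraneous][0]
            tree.reroot_at_edge(node.edge, update_bipartitions=True)
            return tree

    tree.reroot_at_midpoint(update_bipartitions=True)
    return tree


# ----------------------------------------------------- query classification

def _clade_leaf_labels(node: dendropy.Node) -> list[str]:
    return [_leaf_label(lf) for lf in node.leaf_iter()]


def _majority_donor(
    labels: list[str], taxonomy: TaxonomyDB, decision_node: dendropy.Node
) -> str:
    counts: dict[str, int] = {}
    for lab in labels:
        counts[donor_group(taxonomy, lab)] = counts.get(donor_group(taxonomy, lab), 0) + 1
    best = max(counts.values())
    tied = sorted(d for d, c in counts.items() if c == best)
    if len(tied) == 1:
        return tied[0]
    # tie-break by the taxon of the best-supported child clade of the
    # decision node whose majority donor is among the tied labels
    children = sorted(
        decision_node.child_nodes(), key=_support, reverse=True
    )
    for child in children:
        labs = [
            l for l in _clade_leaf_labels(child) if not l.startswith(QUERY_PREFIX)
        ]
        if not labs:
            continue
        sub: dict[str, int] = {}
        for l in labs:
            sub[donor_group(taxonomy, l)] = sub.get(donor_group(taxonomy, l), 0) + 1
        top = sorted(sub, key=lambda d: (-sub[d], d))[0]
        if top in tied:
            return top
    return tied[0]


def classify_query(
    tree: dendropy.Tree,
    taxonomy: TaxonomyDB,
    recipient: str,
    gene_id: str,
    support_min: float = 95.0,
) -> PhyloCall:
    """Classify one rooted gene tree (see module docstring for the rule)."""
    query = _query_leaf(tree)

    def group(label: str) -> GroupLabel:
        return classify_species(taxonomy, label, recipient)

    ingroup_anywhere = any(
        group(_leaf_label(lf)) in (GroupLabel.INGROUP, GroupLabel.SELF)
        for lf in tree.leaf_node_iter()
        if not _leaf_label(lf).startswith(QUERY_PREFIX)
    )

    node = query.parent_node
    while node is not None and node is not tree.seed_node:
        clade = [
            l for l in _clade_leaf_labels(node) if not l.startswith(QUERY_PREFIX)
        ]
        if clade and _support(node) >= support_min:
            groups = {group(l) for l in clade}
            if groups <= {GroupLabel.OUTGROUP}:
                call = Call.HGT if ingroup_anywhere else Call.HGT_NT
                return PhyloCall(
                    gene_id=gene_id,
                    call=call,
                    donor_label=_majority_donor(clade, taxonomy, node),
                    support_at_decision=_support(node),
                )
            return PhyloCall(
                gene_id=gene_id, call=Call.VERTICAL,
                support_at_decision=_support(node),
            )
        node = node.parent_node
    return PhyloCall(gene_id=gene_id, call=Call.UNRESOLVED)


# ------------------------------------------------------------- event merge

def cluster_events(
    calls: list[PhyloCall],
    family_of: dict[str, str],
    species_of: dict[str, str],
) -> tuple[list[HgtEvent], dict[str, int]]:
    """Merge confirmed calls into transfer events.

    Confirmed genes sharing ``(family_id, donor_label)`` form one event; a
    gene without a family assignment becomes its own singleton event (with a
    warning).  Returns the events and a summary with ``n_events``,
    ``n_species_specific`` and ``n_shared`` (always summing to ``n_events``).
    """
    groups: dict[tuple[str, str], HgtEvent] = {}
    singletons: list[HgtEvent] = []
    for call in calls:
        if not call.confirmed:
            continue
        fam = family_of.get(call.gene_id)
        sp = species_of[call.gene_id]
        if fam is None:
            log.warning("gene %s has no family assignment; singleton event",
                        call.gene_id)
            ev = HgtEvent(
                event_id="", family_id=f"__singleton_{call.gene_id}",
                donor_label=call.donor_label,
            )
            ev.gene_ids.append(call.gene_id)
            ev.recipient_species.add(sp)
            singletons.append(ev)
            continue
        key = (fam, call.donor_label)
        ev = groups.setdefault(
            key, HgtEvent(event_id="", family_id=fam, donor_label=call.donor_label)
        )
        ev.gene_ids.append(call.gene_id)
        ev.recipient_species.add(sp)

    events = sorted(
        list(groups.values()) + singletons,
        key=lambda e: (e.family_id, e.donor_label),
    )
    for i, ev in enumerate(events):
        ev.event_id = f"event_{i:05d}"
    n_specific = sum(1 for e in events if e.species_specific)
    summary = {
        "n_events": len(events),
        "n_species_specific": n_specific,
        "n_shared": len(events) - n_specific,
    }
    return events, summary
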