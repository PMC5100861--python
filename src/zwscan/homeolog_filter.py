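"""Phylogeny-based separation of orthologs from homeologs in allotetraploid
gene families.

Because the allotetraploid ingroup species all descend from one whole-genome
duplication that predates their speciation, orthologous copies are more
closely related to each other than to homeologous copies.  A gene tree that
splits the ingroup sequences into two groups — each with at most one
sequence per species, at least one species represented in both, and at
least one group with three or more sequences — is therefore evidence of a
clean ortholog/homeolog partition.  Families are screened by alignment QC
(ungapped length, ingroup species counts), trees are built by
neighbor-joining on pairwise-deletion p-distances (or supplied externally),
and assessment runs for up to three build/assess rounds, pruning
near-identical same-species tips (splice variants, assembly duplicates)
between rounds.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Optional

import dendropy
import numpy as np

from .errors import AlignmentError

GAP = ord("-")

UNASSESSED = "unassessed"
ACCEPTED = "accepted"
REJECTED = "rejected"


@dataclass
class GeneFamily:
    """A species-tagged alignment with an optional gene tree.

    ``partition`` (set when accepted) is a pair of frozensets of ingroup
    sequence names: the two homeologous lineages, orthologs within each.
    """

    family_id: str
    names: list  # ordered sequence names
    sequences: dict  # name -> aligned sequence (equal lengths)
    species: dict  # name -> species label
    tree: Optional[dendropy.Tree] = None
    status: str = UNASSESSED
    rejection_reason: Optional[str] = None
    partition: Optional[tuple] = None

    def __post_init__(self) -> None:
        lengths = {len(self.sequences[n]) for n in self.names}
        if len(lengths) > 1:
            raise AlignmentError(
                f"{self.family_id}: ragged alignment (lengths {sorted(lengths)})"
            )

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[self.names[0]]) if self.names else 0

    def ingroup_names(self, outgroup_species: Optional[str]) -> list:
        return [n for n in self.names if self.species[n] != outgroup_species]

    def ungapped_seq_length(self, name: str) -> int:
        return sum(1 for ch in self.sequences[name] if ch != "-")

    def without(self, drop: Iterable[str]) -> "GeneFamily":
        drop = set(drop)
        names = [n for n in self.names if n not in drop]
        return GeneFamily(
            family_id=self.family_id,
            names=names,
            sequences={n: self.sequences[n] for n in names},
            species={n: self.species[n] for n in names},
            tree=None,  # tree no longer matches; must be rebuilt
        )


@dataclass
class FilterConfig:
    """Screening thresholds.

    min_ungapped_bp: minimum number of alignment columns free of gaps in
        every retained sequence (the default 300 means strictly more than
        299 bp survive).
    near_identical_p: p-distance at or below which two same-species tips
        are treated as duplicates of one transcript (splice variants or
        assembly artifacts) and pruned to the longest.
    """

    min_ungapped_bp: int = 300
    min_ingroup_species: int = 3
    max_rounds: int = 3
    outgroup_species: Optional[str] = None
    near_identical_p: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass
class QCResult:
    passed: bool
    reason: Optional[str] = None
    ungapped_length: int = 0
    n_ingroup_species: int = 0


def ungapped_length(family: GeneFamily) -> int:
    """Columns containing no gap character in any sequence of the family."""
    if not family.names:
        return 0
    arr = _seq_matrix(family)
    return int(np.sum(np.all(arr != GAP, axis=0)))


def alignment_qc(family: GeneFamily, config: Optional[FilterConfig] = None) -> QCResult:
    """Length and taxon-sampling screen applied before any tree is built."""
    config = config or FilterConfig()
    ingroup = family.ingroup_names(config.outgroup_species)
    species_counts: dict = {}
    for n in ingroup:
        species_counts[family.species[n]] = species_counts.get(family.species[n], 0) + 1
    n_species = len(species_counts)
    ug = ungapped_length(family)
    if ug < config.min_ungapped_bp:
        return QCResult(False, f"ungapped_length_{ug}_below_{config.min_ungapped_bp}",
                        ug, n_species)
    if n_species < config.min_ingroup_species:
        return QCResult(False, f"only_{n_species}_ingroup_species", ug, n_species)
    if not any(c >= 2 for c in species_counts.values()):
        return QCResult(False, "no_species_with_two_sequences", ug, n_species)
    return QCResult(True, None, ug, n_species)


# ---------------------------------------------------------------------------
# Distances and neighbor-joining
# ---------------------------------------------------------------------------


def _seq_matrix(family: GeneFamily) -> np.ndarray:
    return np.frombuffer(
        "".join(family.sequences[n] for n in family.names).encode(), dtype=np.uint8
    ).reshape(len(family.names), family.alignment_length)


def p_distance_matrix(family: GeneFamily) -> tuple:
    """Pairwise p-distances with pairwise deletion of gap columns.

    Returns (names, matrix); a pair with zero comparable columns raises,
    naming the pair.
    """
    names = family.names
    arr = _seq_matrix(family)
    n = len(names)
    dist = np.zeros((n, n))
    present = arr != GAP
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            m = int(both.sum())
            if m == 0:
                raise AlignmentError(
                    f"{family.family_id}: sequences {names[i]!r} and {names[j]!r} "
                    f"share no comparable (gap-free) columns"
                )
            diff = int(np.sum(arr[i, both] != arr[j, both]))
            dist[i, j] = dist[j, i] = diff / m
    return names, dist


def build_nj_tree(family: GeneFamily) -> dendropy.Tree:
    """Unrooted neighbor-joining tree from pairwise-deletion p-distances.

    Saitou-Nei agglomeration with the canonical Q criterion.  Sequence
    names are sorted before the matrix is assembled and ties in Q are
    broken by the first (i, j) pair in that order, so the result is fully
    deterministic.  The last three lineages are joined at a trifurcating
    root with the three-point branch lengths, giving the standard unrooted
    representation.
    """
    if len(family.names) < 3:
        raise AlignmentError(
            f"{family.family_id}: need >= 3 sequences for a tree, "
            f"have {len(family.names)}"
        )
    ordered = sorted(family.names)
    view = GeneFamily(
        family_id=family.family_id,
        names=ordered,
        sequences=family.sequences,
        species=family.species,
    )
    names, dist = p_distance_matrix(view)
    d = dist.copy()
    subtrees = [f"'{n}'" for n in names]
    active = list(range(len(names)))

    while len(active) > 3:
        n = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        merged = f"({subtrees[i]}:{li:.12g},{subtrees[j]}:{lj:.12g})"
        for k in active:
            if k not in (i, j):
                d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        subtrees[i] = merged
        active.remove(j)

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    newick = (f"({subtrees[i]}:{li:.12g},{subtrees[j]}:{lj:.12g},"
              f"{subtrees[k]}:{lk:.12g});")
    return dendropy.Tree.get(data=newick, schema="newick")


# ---------------------------------------------------------------------------
# Assessment
# ---------------------------------------------------------------------------


@dataclass
class Assessment:
    kind: str  # accept | reject | prune
    partition: Optional[tuple] = None
    reason: Optional[str] = None
    tips_to_drop: list = field(default_factory=list)


def _rooted_clone(family: GeneFamily, config: FilterConfig) -> dendropy.Tree:
    tree = family.tree.clone(depth=1)
    out_leaves = [
        lf for lf in tree.leaf_node_iter()
        if family.species.get(lf.taxon.label) == config.outgroup_species
    ]
    if out_leaves:
        if len(out_leaves) == 1:
            tree.reroot_at_edge(out_leaves[0].edge, update_bipartitions=False)
        else:
            mrca = tree.mrca(taxa=[lf.taxon for lf in out_leaves])
            if mrca is not tree.seed_node:
                tree.reroot_at_edge(mrca.edge, update_bipartitions=False)
    else:
        if len(tree.leaf_nodes()) <= 2:
            raise AlignmentError(
                f"{family.family_id}: cannot midpoint-root a tree with <= 2 tips"
            )
        tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


def _valid_partition(group1: frozenset, group2: frozenset, species: dict) -> bool:
    """Criteria: (a) <= 1 tip per species per group; (b) >= 1 species present
    in both groups; (c) >= 1 group with >= 3 tips."""
    if not group1 or not group2:
        return False
    sp1 = [species[n] for n in group1]
    sp2 = [species[n] for n in group2]
    if len(sp1) != len(set(sp1)) or len(sp2) != len(set(sp2)):
        return False
    if not set(sp1) & set(sp2):
        return False
    return max(len(group1), len(group2)) >= 3


def _near_identical_clusters(family: GeneFamily, config: FilterConfig) -> list:
    """Same-species tip clusters within p-distance near_identical_p."""
    names, dist = p_distance_matrix(family)
    ingroup = set(family.ingroup_names(config.outgroup_species))
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            if (a in ingroup and b in ingroup
                    and family.species[a] == family.species[b]
                    and dist[i, j] <= config.near_identical_p):
                parent[find(a)] = find(b)
    clusters: dict = {}
    for n in names:
        clusters.setdefault(find(n), []).append(n)
    return [sorted(c) for c in clusters.values() if len(c) > 1]


def assess_homeology(family: GeneFamily, config: Optional[FilterConfig] = None
                     ) -> Assessment:
    """Search the rooted gene tree for a valid ortholog/homeolog bipartition.

    Internal edges are visited in pre-order from the root, so the first
    valid split found is the one closest to the root (deterministic).  This
    matters: below the genome-duplication node, a nested clade of one
    homeolog lineage can also satisfy the criteria, but the duplication
    split is its ancestor and is always reached first from the root.  When no edge qualifies but a species carries
    near-identical duplicate tips, those are pruned to the longest
    (ungapped) representative and a rebuild is requested; otherwise the
    family is rejected with a diagnostic reason.
    """
    config = config or FilterConfig()
    if family.tree is None:
        raise AlignmentError(f"{family.family_id}: no tree attached")
    tree = _rooted_clone(family, config)
    ingroup_all = frozenset(family.ingroup_names(config.outgroup_species))

    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        below = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        ) & ingroup_all
        above = ingroup_all - below
        if _valid_partition(below, above, family.species):
            return Assessment("accept", partition=(below, above))

    clusters = _near_identical_clusters(family, config)
    if clusters:
        drop = []
        for cluster in clusters:
            keep = max(cluster, key=lambda n: (family.ungapped_seq_length(n), n))
            drop += [n for n in cluster if n != keep]
        return Assessment("prune", tips_to_drop=sorted(drop))

    counts: dict = {}
    for n in ingroup_all:
        counts[family.species[n]] = counts.get(family.species[n], 0) + 1
    if not any(c >= 2 for c in counts.values()):
        return Assessment("reject", reason="no_species_with_two_sequences")
    # duplicated species whose copies are mutually closest (sister tips) look
    # like lineage-specific duplication, not genome duplication
    dup_species = {s for s, c in counts.items() if c >= 2}
    for node in tree.postorder_internal_node_iter():
        kids = node.child_nodes()
        leaves = [k for k in kids if k.is_leaf()]
        if len(leaves) >= 2:
            sp = {family.species[lf.taxon.label] for lf in leaves}
            if len(sp) == 1 and sp <= dup_species:
                return Assessment("reject", reason="sister_duplicates")
    return Assessment("reject", reason="no_valid_partition")


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


@dataclass
class AuditRecord:
    family_id: str
    status: str
    reason: Optional[str]
    rounds_used: int
    partition: Optional[tuple]


def run_filter(families: Iterable[GeneFamily],
               config: Optional[FilterConfig] = None) -> tuple:
    """QC, build/assess (up to max_rounds), prune-and-rebuild loop.

    Returns (accepted families, audit records); every input family appears
    exactly once in the audit.  Provided trees are used on the first round;
    rebuilds after pruning always use the built-in neighbor-joining.
    """
    config = config or FilterConfig()
    accepted, audit = [], []
    for family in families:
        current = family
        rounds = 0
        status, reason, partition = REJECTED, None, None
        while True:
            qc = alignment_qc(current, config)
            if not qc.passed:
                reason = qc.reason
                break
            if len(current.names) < 3:
                reason = "too_few_sequences"
                break
            if rounds >= config.max_rounds:
                reason = "unresolved_after_rounds"
                break
            if current.tree is None:
                current.tree = build_nj_tree(current)
            rounds += 1
            result = assess_homeology(current, config)
            if result.kind == "accept":
                status, partition = ACCEPTED, result.partition
                break
            if result.kind == "reject":
                reason = result.reason
                break
            current = current.without(result.tips_to_drop)
        current.status = status
        current.rejection_reason = reason
        current.partition = partition
        audit.append(AuditRecord(family.family_id, status, reason, rounds, partition))
        if status == ACCEPTED:
            accepted.append(current)
    return accepted, audit


def write_audit_tsv(audit: list, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tstatus\treason\trounds_used\tpartition\n")
        for rec in audit:
            part = ""
            if rec.partition:
                part = "|".join(",".join(sorted(g)) for g in rec.partition)
            fh.write(
                f"{rec.family_id}\t{rec.status}\t{rec.reason or ''}\t"
                f"{rec.rounds_used}\t{part}\n"
            )


def select_for_coalescent(family: GeneFamily, required_species: set,
                          seed: int = 0) -> tuple:
    """Reduce an accepted family to one complete ortholog set plus a single
    homeolog anchor from the other lineage.

    The "complete" lineage must have an ortholog for every required species;
    from the other lineage only the longest (ungapped) sequence is kept,
    with a seeded random choice among equal-length ties.  Returns
    (reduced family, "ok") or (None, reason).
    """
    if family.status != ACCEPTED or family.partition is None:
        return None, "not_accepted"
    required = set(required_species)
    complete = other = None
    for idx, group in enumerate(family.partition):
        covered = {family.species[n] for n in group}
        if required <= covered:
            complete = group
            other = family.partition[1 - idx]
            break
    if complete is None:
        return None, "no_complete_lineage"
    if not other:
        return None, "no_other_lineage"
    lengths = {n: family.ungapped_seq_length(n) for n in other}
    top = max(lengths.values())
    ties = sorted(n for n, l in lengths.items() if l == top)
    pick = ties[0] if len(ties) == 1 else random.Random(seed).choice(ties)
    keep = sorted(complete) + [pick]
    reduced = GeneFamily(
        family_id=family.family_id,
        names=[n for n in family.names if n in set(keep)],
        sequences={n: family.sequences[n] for n in keep},
        species={n: family.species[n] for n in keep},
        status=ACCEPTED,
        partition=(frozenset(complete), frozenset({pick})),
    )
    return reduced, "ok"
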