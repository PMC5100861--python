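"""Synthetic data with ground truth for every downstream stage.

Two generators:

* :func:`simulate_family` — GBS-style biallelic tag genotypes for an F1
  cross (two parents, 24 daughters + 23 sons by default).  Autosomal loci
  segregate Mendelianly and independently of offspring sex.  Sex-linked
  loci live in a non-recombining region: under ZW, a W-borne variant makes
  the mother and all daughters heterozygous; a variant private to one
  maternal Z makes the mother and all sons heterozygous.  XY mirrors both
  with the father.  Genotyping error is modeled as heterozygote undercall
  (allele dropout): a heterozygote is read as one of its two homozygotes
  with equal probability.  Parents, sequenced at ~10x the offspring
  coverage, get the offspring error rates scaled down by
  ``parent_error_scale``.

* :func:`simulate_gene_families` — gene families evolved under Jukes-Cantor
  along a species tree whose genome was duplicated before the ingroup
  speciated (allotetraploidy), with per-branch homeolog loss and optional
  near-duplicate "splice variant" tips, so ortholog/homeolog partitions are
  known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

from .errors import ConfigError
from .io_formats import FamilyDataset, Individual, LocusRecord, genotype

NUCLEOTIDES = ("A", "C", "G", "T")

AUTOSOMAL = "autosomal"
W_LINKED = "W_linked"
Z_LINKED = "Z_linked"
X_LINKED = "X_linked"
Y_LINKED = "Y_linked"

# Ordered (mother, father) genotype-class pairs over {0: ref/ref, 1: het,
# 2: alt/alt} that leave the family polymorphic; ref/ref x ref/ref and
# alt/alt x alt/alt are excluded because reference-free SNP callers only
# report polymorphic tags.
POLYMORPHIC_PARENT_CONFIGS = tuple(
    (m, f) for m in range(3) for f in range(3) if not (m == f and m != 1)
)
assert len(POLYMORPHIC_PARENT_CONFIGS) == 7

_CLASS_TO_PAIR = {0: (0, 0), 1: (0, 1), 2: (1, 1)}  # genotype class -> allele picks


@dataclass
class FamilySimConfig:
    """Study conditions for the family simulator.

    Counts default to the cross design this pipeline targets: 24 daughters
    and 23 sons.  ``n_sexlinked`` loci carry a variant on the sex-limited
    chromosome (W under ZW, Y under XY); ``n_sexlinked_shared`` loci carry a
    variant private to one copy of the shared chromosome of the
    heterogametic parent (one maternal Z, or the paternal X).
    """

    n_daughters: int = 24
    n_sons: int = 23
    n_autosomal: int = 0
    n_sexlinked: int = 0
    n_sexlinked_shared: int = 0
    system: Optional[str] = None  # "ZW" | "XY"
    undercall_rate: float = 0.0
    missing_rate: float = 0.0
    parent_error_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("undercall_rate", "missing_rate", "parent_error_scale"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_daughters", "n_sons", "n_autosomal", "n_sexlinked",
                     "n_sexlinked_shared"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if (self.n_sexlinked or self.n_sexlinked_shared) and self.system not in ("ZW", "XY"):
            raise ConfigError("sex-linked loci requested but system is not ZW or XY")
        if self.system not in (None, "ZW", "XY"):
            raise ConfigError(f"unknown system {self.system!r}")


@dataclass
class TruthRecord:
    locus_id: str
    locus_class: str  # autosomal | W_linked | Z_linked | X_linked | Y_linked
    true_genotypes: list  # pre-error genotype per individual (pedigree order)


@dataclass
class TruthTable:
    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.by_locus = {r.locus_id: r for r in self.records}

    def loci_of_class(self, locus_class: str) -> set:
        return {r.locus_id for r in self.records if r.locus_class == locus_class}

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("locus_id\tclass\ttrue_genotypes\n")
            for r in self.records:
                gts = ",".join(f"{g[0]}/{g[1]}" for g in r.true_genotypes)
                fh.write(f"{r.locus_id}\t{r.locus_class}\t{gts}\n")


def _make_individuals(config: FamilySimConfig) -> list:
    inds = [Individual("mother", "mother", "F"), Individual("father", "father", "M")]
    inds += [Individual(f"d{i + 1:02d}", "offspring", "F") for i in range(config.n_daughters)]
    inds += [Individual(f"s{i + 1:02d}", "offspring", "M") for i in range(config.n_sons)]
    return inds


def _apply_errors(cls: np.ndarray, undercall: float, missing: float,
                  rng: np.random.Generator) -> tuple:
    """Genotype classes (0 hom-ref, 1 het, 2 hom-alt) -> observed classes + mask.

    Undercall turns a heterozygote into either homozygote with probability
    1/2 each; missingness is applied after undercall.
    """
    obs = cls.copy()
    het = obs == 1
    drop = het & (rng.random(obs.shape) < undercall)
    direction = rng.integers(0, 2, size=obs.shape) * 2  # 0 or 2
    obs[drop] = direction[drop]
    miss = rng.random(obs.shape) < missing
    return obs, miss


def simulate_family(config: FamilySimConfig) -> tuple:
    """Simulate an F1 cross; returns (FamilyDataset, TruthTable)."""
    rng = np.random.default_rng(config.seed)
    individuals = _make_individuals(config)
    nd, ns = config.n_daughters, config.n_sons
    n_off = nd + ns
    n_auto = config.n_autosomal
    n_limited = config.n_sexlinked  # W or Y
    n_shared = config.n_sexlinked_shared  # maternal Z or paternal X
    n_loci = n_auto + n_limited + n_shared

    # -- true genotype classes, loci x individuals (mother, father, offspring)
    mother_cls = np.empty(n_loci, dtype=np.int8)
    father_cls = np.empty(n_loci, dtype=np.int8)
    off_cls = np.empty((n_loci, n_off), dtype=np.int8)
    classes = []

    if n_auto:
        cfg_idx = rng.integers(0, len(POLYMORPHIC_PARENT_CONFIGS), size=n_auto)
        configs = np.asarray(POLYMORPHIC_PARENT_CONFIGS)[cfg_idx]
        mother_cls[:n_auto] = configs[:, 0]
        father_cls[:n_auto] = configs[:, 1]
        pair = np.asarray([_CLASS_TO_PAIR[c] for c in range(3)])  # class -> 2 alleles
        m_gam = pair[configs[:, 0]]  # (n_auto, 2) allele indices carried by mother
        f_gam = pair[configs[:, 1]]
        m_pick = rng.integers(0, 2, size=(n_auto, n_off))
        f_pick = rng.integers(0, 2, size=(n_auto, n_off))
        rows = np.arange(n_auto)[:, None]
        a = m_gam[rows, m_pick]
        b = f_gam[rows, f_pick]
        off_cls[:n_auto] = (a + b).astype(np.int8)
        classes += [AUTOSOMAL] * n_auto

    # Sex-linked loci: the heterogametic parent is het (ref = shared allele,
    # alt = chromosome-specific allele), the other parent hom-ref.  On the
    # sex-limited chromosome the variant goes to all offspring of the
    # heterogametic parent's sex... concretely:
    #   ZW, W-borne:  mother het; daughters het, sons hom-ref.
    #   ZW, Z-borne:  mother het; sons het, daughters hom-ref.
    #   XY, Y-borne:  father het; sons het, daughters hom-ref.
    #   XY, X-borne:  father het; daughters het, sons hom-ref.
    daughter_mask = np.array([1] * nd + [0] * ns, dtype=np.int8)
    for k in range(n_limited + n_shared):
        i = n_auto + k
        limited = k < n_limited
        if config.system == "ZW":
            mother_cls[i], father_cls[i] = 1, 0
            het_daughters = limited  # W -> daughters; maternal Z -> sons
            classes.append(W_LINKED if limited else Z_LINKED)
        else:
            mother_cls[i], father_cls[i] = 0, 1
            het_daughters = not limited  # Y -> sons; paternal X -> daughters
            classes.append(Y_LINKED if limited else X_LINKED)
        off_cls[i] = daughter_mask if het_daughters else 1 - daughter_mask

    # -- allele symbols per locus: two distinct nucleotides
    ref_idx = rng.integers(0, 4, size=n_loci)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_loci)) % 4

    # -- observation model
    u, m = config.undercall_rate, config.missing_rate
    scale = config.parent_error_scale
    obs_off, miss_off = _apply_errors(off_cls, u, m, rng)
    parent_cls = np.stack([mother_cls, father_cls], axis=1)
    obs_par, miss_par = _apply_errors(parent_cls, u * scale, m * scale, rng)

    # -- shuffle locus order so position does not encode the locus class
    order = rng.permutation(n_loci)

    loci, truth_records = [], []
    for rank, i in enumerate(order):
        ref, alt = NUCLEOTIDES[ref_idx[i]], NUCLEOTIDES[alt_idx[i]]
        lookup = (genotype(ref, ref), genotype(ref, alt), genotype(alt, alt))
        locus_id = f"tag{rank + 1:06d}"
        true_gts = [lookup[mother_cls[i]], lookup[father_cls[i]]]
        true_gts += [lookup[c] for c in off_cls[i]]
        obs = [
            None if miss_par[i, 0] else lookup[obs_par[i, 0]],
            None if miss_par[i, 1] else lookup[obs_par[i, 1]],
        ]
        row_obs, row_miss = obs_off[i], miss_off[i]
        obs += [None if row_miss[j] else lookup[row_obs[j]] for j in range(n_off)]
        alleles = frozenset(a for gt in obs if gt is not None for a in gt)
        loci.append(LocusRecord(locus_id, alleles, obs))
        truth_records.append(TruthRecord(locus_id, classes[i], true_gts))

    return FamilyDataset(individuals, loci), TruthTable(truth_records)


# ---------------------------------------------------------------------------
# Gene families on a duplicated species tree
# ---------------------------------------------------------------------------

#: Ultrametric ingroup species tree (5 allotetraploid frogs), crown depth 1.0.
DEFAULT_INGROUP_TREE = "((((xlae:0.25,xbor:0.25):0.25,xcli:0.5):0.25,xall:0.75):0.25,xlar:1.0);"
DEFAULT_OUTGROUP = "xtro"
DEFAULT_OUTGROUP_DEPTH = 2.0


@dataclass
class GeneFamSimConfig:
    """Gene-family simulator conditions.

    The genome duplication sits ``wgd_stem`` time units above the ingroup
    crown on the ingroup stem; the whole ingroup radiation is therefore more
    recent than the duplication, so orthologs are always more closely
    related than homeologs.  ``subst_rate`` is in substitutions per site per
    tree time unit (the default tree's ingroup crown is at depth 1.0, the
    outgroup at 2.0).  ``loss_prob`` applies independently to every branch
    of each duplicated ingroup copy, including its stem; a loss deletes all
    descendant tips of that copy.  ``splice_variant_prob`` is the chance a
    family gains one near-identical duplicate of a surviving tip (>= 99%
    identity; modeled as a gap-truncated copy, mimicking an alternative
    transcript or assembly artifact).
    """

    ingroup_tree: str = DEFAULT_INGROUP_TREE
    outgroup: str = DEFAULT_OUTGROUP
    outgroup_depth: float = DEFAULT_OUTGROUP_DEPTH
    wgd_stem: float = 0.3
    n_families: int = 100
    loss_prob: float = 0.0
    splice_variant_prob: float = 0.0
    subst_rate: float = 0.1
    seq_length: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length < 1:
            raise ConfigError("seq_length must be >= 1")
        for name in ("loss_prob", "splice_variant_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.wgd_stem <= 0:
            raise ConfigError("wgd_stem must be > 0 (duplication precedes speciation)")


@dataclass
class _Node:
    """Lightweight gene-tree node for simulation."""

    name: Optional[str]
    length: float  # branch above this node, in tree time units
    children: list = field(default_factory=list)

    def leaves(self) -> list:
        if not self.children:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:g}"


def _ingroup_to_node(tree: dendropy.Tree, copy_label: str, stem: float) -> _Node:
    def convert(nd) -> _Node:
        length = nd.edge.length or 0.0
        if nd.is_leaf():
            return _Node(f"{nd.taxon.label}|{copy_label}", length)
        out = _Node(None, length)
        out.children = [convert(c) for c in nd.child_nodes()]
        return out

    root = convert(tree.seed_node)
    root.length = stem
    return root


def _depth(tree: dendropy.Tree) -> float:
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def _build_gene_tree(config: GeneFamSimConfig) -> _Node:
    try:
        ingroup = dendropy.Tree.get(data=config.ingroup_tree, schema="newick")
    except Exception as exc:
        raise ConfigError(f"unparseable ingroup tree: {exc}") from exc
    tips = [lf for lf in ingroup.leaf_node_iter() if lf.taxon is not None]
    if not tips:
        raise ConfigError("ingroup tree has no tips")
    crown_depth = _depth(ingroup)
    wgd_depth = crown_depth + config.wgd_stem
    if wgd_depth >= config.outgroup_depth:
        raise ConfigError("duplication must postdate the outgroup split")
    copy1 = _ingroup_to_node(ingroup, "c1", config.wgd_stem)
    copy2 = _ingroup_to_node(ingroup, "c2", config.wgd_stem)
    wgd = _Node(None, config.outgroup_depth - wgd_depth, [copy1, copy2])
    out_tip = _Node(f"{config.outgroup}|c1", config.outgroup_depth)
    return _Node(None, 0.0, [out_tip, wgd])


def _jc69_evolve(parent_seq: np.ndarray, d: float, rng: np.random.Generator
                 ) -> np.ndarray:
    """One Jukes-Cantor branch: d expected substitutions/site."""
    p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    seq = parent_seq.copy()
    hit = rng.random(seq.shape) < p_change
    seq[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return seq


@dataclass
class GeneFamilyTruth:
    family_id: str
    tree_newick: str
    partition: tuple  # (frozenset copy1 ingroup tips, frozenset copy2 tips)
    splice_variants: list  # injected near-duplicate tip names
    n_ingroup_species_present: int
    has_both_copies: bool


def simulate_gene_families(config: GeneFamSimConfig) -> list:
    """Return a list of (GeneFamily, GeneFamilyTruth) pairs.

    Sequences are byte-identical across runs for a fixed seed.
    """
    from .homeolog_filter import GeneFamily

    rng = np.random.default_rng(config.seed)
    results = []
    for fam_idx in range(config.n_families):
        tree = _build_gene_tree(config)
        out_tip, wgd = tree.children

        # per-branch homeolog loss inside each duplicated copy (incl. stems)
        surviving_by_copy = []
        for copy_root in wgd.children:
            lost_tips: set = set()

            def walk(node: _Node, lost_above: bool) -> None:
                lost = lost_above or (rng.random() < config.loss_prob)
                if not node.children:
                    if lost:
                        lost_tips.add(node.name)
                    return
                for c in node.children:
                    walk(c, lost)

            walk(copy_root, False)
            surviving_by_copy.append(
                frozenset(lf.name for lf in copy_root.leaves()) - lost_tips
            )

        # evolve sequences down the full gene tree, then drop lost tips
        seqs: dict = {}

        def evolve(node: _Node, parent_seq: np.ndarray) -> None:
            d = node.length * config.subst_rate
            seq = _jc69_evolve(parent_seq, d, rng) if d > 0 else parent_seq.copy()
            if not node.children:
                seqs[node.name] = seq
                return
            for c in node.children:
                evolve(c, seq)

        root_seq = rng.integers(0, 4, size=config.seq_length)
        evolve(tree, root_seq)

        keep = {out_tip.name} | surviving_by_copy[0] | surviving_by_copy[1]
        names = sorted(n for n in seqs if n in keep)
        alignment = {
            n: "".join(NUCLEOTIDES[b] for b in seqs[n]) for n in names
        }

        # optional splice-variant injection: a gap-truncated near-duplicate
        variants = []
        ingroup_names = [n for n in names if not n.startswith(config.outgroup)]
        if ingroup_names and rng.random() < config.splice_variant_prob:
            src = ingroup_names[rng.integers(0, len(ingroup_names))]
            gap_len = max(1, config.seq_length // 20)
            start = int(rng.integers(0, config.seq_length - gap_len + 1))
            s = list(alignment[src])
            s[start:start + gap_len] = "-" * gap_len
            var_name = src + "v"
            alignment[var_name] = "".join(s)
            names.append(var_name)
            names.sort()
            variants.append(var_name)

        family_id = f"fam{fam_idx + 1:04d}"
        species = {n: n.split("|", 1)[0] for n in names}
        family = GeneFamily(
            family_id=family_id,
            names=names,
            sequences=alignment,
            species=species,
        )
        ingroup_species = {species[n] for n in names if species[n] != config.outgroup}
        truth = GeneFamilyTruth(
            family_id=family_id,
            tree_newick=tree.newick() + ";",
            partition=(surviving_by_copy[0], surviving_by_copy[1]),
            splice_variants=variants,
            n_ingroup_species_present=len(ingroup_species),
            has_both_copies=bool(surviving_by_copy[0]) and bool(surviving_by_copy[1]),
        )
        results.append((family, truth))
    return results
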