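"""Synthetic COI barcode datasets with known truth, for desk-scale testing.

The generator emulates a multi-species barcode survey: a Yule tree over
species (scaled to a target interspecific divergence), star-like
within-species subtrees at a much smaller depth, an optional fraction of
species carrying a planted deep intraspecific split, a basal outgroup, and
sequence evolution under HKY with optional invariant sites and
gamma-distributed rate heterogeneity. Contaminant pseudogene (NUMT)
sequences can be injected by writing an in-frame stop codon into a random
codon. Every run is reproducible from its seed, and a truth table records
what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .seqio import MITO_STOPS, Alignment, SequenceRecord

BASES = "ACGT"
_STOP_LIST = sorted(MITO_STOPS)


@dataclass
class SimulationConfig:
    """Generator settings; defaults describe a temperate-zone COI survey.

    ``interspecific_height`` and ``intraspecific_height`` are expected
    divergences in substitutions/site between (resp. within) species;
    ``geometric_p`` controls the truncated-geometric number of individuals
    per species on 1..``max_individuals``. ``gamma_alpha=None`` disables
    rate heterogeneity.
    """

    n_species: int = 40
    geometric_p: float = 0.4
    max_individuals: int = 17
    length: int = 443
    kappa: float = 8.0
    base_freq: dict[str, float] = field(
        default_factory=lambda: {"A": 0.247, "C": 0.333, "G": 0.154, "T": 0.265}
    )
    p_inv: float = 0.5
    gamma_alpha: float | None = 0.3
    interspecific_height: float = 0.12
    intraspecific_height: float = 0.003
    min_species_separation: float = 0.013
    deep_split_fraction: float = 0.0
    deep_split_height: float = 0.044
    numt_rate: float = 0.0
    outgroup: bool = True
    preserve_reading_frame: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not 0.0 < self.geometric_p <= 1.0:
            raise ValueError("geometric_p must lie in (0, 1]")
        total = sum(self.base_freq.get(b, 0.0) for b in BASES)
        if abs(total - 1.0) > 0.01:
            raise ValueError("base frequencies must sum to 1")
        if abs(total - 1.0) > 1e-12:  # tolerate rounded published compositions
            self.base_freq = {b: self.base_freq[b] / total for b in BASES}
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must lie in [0, 1)")
        if not 0.0 <= self.numt_rate < 1.0:
            raise ValueError("numt_rate must lie in [0, 1)")
        if self.intraspecific_height >= self.interspecific_height:
            import warnings

            warnings.warn(
                "intraspecific height >= interspecific height: "
                "species will not be separable"
            )

    def pi(self) -> np.ndarray:
        return np.array([self.base_freq[b] for b in BASES])


def chile_coi(seed: int = 0, **overrides) -> SimulationConfig:
    """Preset spanning the divergence regimes of a temperate Chilean bird
    COI survey: 76 species, 443 sites, ~2.6 individuals/species (1-17),
    within-species divergence ~0.3%, between-species ~1-44%, a few species
    with a planted deep split, reading frame preserved."""
    base = dict(
        n_species=76,
        geometric_p=0.4,
        length=443,
        kappa=8.0,
        p_inv=0.5,
        gamma_alpha=1.0,
        interspecific_height=0.35,
        intraspecific_height=0.003,
        min_species_separation=0.013,
        deep_split_fraction=3 / 76,
        deep_split_height=0.09,
        preserve_reading_frame=True,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class TruthTable:
    """What the generator planted: per-species truth and contaminant ids."""

    species_of: dict[str, str]  # individual id -> species
    monophyletic: dict[str, bool]  # species -> generating-tree monophyly
    true_intra_divergence: dict[str, float]  # species -> mean within-species tree distance
    deep_split_species: list[str]
    contaminant_ids: list[str]
    outgroup_id: str | None

    def pair_distances(self, tree: dendropy.Tree) -> pd.DataFrame:
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        rows = []
        labels = sorted(taxa)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                rows.append(
                    {"id_a": a, "id_b": b, "tree_distance": pdm.patristic_distance(taxa[a], taxa[b])}
                )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp in sorted(self.monophyletic):
            rows.append(
                {
                    "species": sp,
                    "monophyletic": self.monophyletic[sp],
                    "true_intra_divergence": self.true_intra_divergence.get(sp, 0.0),
                    "deep_split": sp in self.deep_split_species,
                }
            )
        return pd.DataFrame(rows)


def _sample_individuals(config: SimulationConfig, rng: np.random.Generator) -> list[int]:
    """Truncated-geometric individuals-per-species counts on 1..max."""
    counts = []
    for _ in range(config.n_species):
        k = int(rng.geometric(config.geometric_p))
        while k > config.max_individuals:
            k = int(rng.geometric(config.geometric_p))
        counts.append(k)
    return counts


def _yule_tree(n: int, rng: np.random.Generator) -> tuple[dendropy.Node, dict, float]:
    """Pure-birth tree shape; returns (root node, birth-time map, tip time)."""
    root = dendropy.Node()
    t = 0.0
    birth = {root: 0.0}
    active = [root]
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth[child] = t
            active.append(child)
    t += rng.exponential(1.0 / len(active))
    # edge lengths: internal = child first-split - own birth; leaves extend to t
    for node in list(birth):
        if node.child_nodes():
            end = birth[node.child_nodes()[0]]
        else:
            end = t
        if node is not root:
            node.edge.length = end - birth[node]
    return root, birth, t


def _mean_pairwise_leaf_distance(tree: dendropy.Tree) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [lf.taxon for lf in tree.leaf_node_iter()]
    vals = [
        pdm.patristic_distance(taxa[i], taxa[j])
        for i in range(len(taxa))
        for j in range(i + 1, len(taxa))
    ]
    return float(np.mean(vals))


def simulate_species_tree(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dendropy.Tree, TruthTable]:
    """Individual-level genealogy: scaled Yule species tree + star subtrees.

    The Yule tree is rescaled so the mean pairwise path length between
    species equals twice ``interspecific_height``. A random
    ``deep_split_fraction`` of the multi-individual species receive a
    bimodal within-species split at ``deep_split_height`` divergence. The
    outgroup hangs from a new basal root on a long pendant edge.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    root, _, _ = _yule_tree(config.n_species, rng)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root

    species_leaves = [lf for lf in tree.leaf_node_iter()]
    # temporary taxa so the distance matrix can be computed for scaling
    for i, lf in enumerate(species_leaves):
        lf.taxon = tns.new_taxon(f"tmp{i}")
    scale = 2.0 * config.interspecific_height / _mean_pairwise_leaf_distance(tree)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    # enforce a floor on between-species divergence (recent Yule splits
    # would otherwise produce effectively indistinguishable species)
    for lf in species_leaves:
        lf.edge.length = (lf.edge.length or 0.0) + config.min_species_separation / 2.0
    for lf in species_leaves:
        lf.taxon = None
    tns2 = dendropy.TaxonNamespace()
    tree.taxon_namespace = tns2

    counts = _sample_individuals(config, rng)
    multi = [i for i, c in enumerate(counts) if c >= 2]
    n_deep = int(round(config.deep_split_fraction * config.n_species))
    # plant deep splits in lightly sampled species (deep intraspecific
    # lineages are typically seen in surveys with few individuals per species)
    multi_small = sorted(multi, key=lambda i: (counts[i], i))[: max(2 * n_deep, len(multi) // 2)]
    deep_idx = set(
        rng.choice(multi_small, size=min(n_deep, len(multi_small)), replace=False).tolist()
    )

    species_of: dict[str, str] = {}
    true_intra: dict[str, float] = {}
    deep_species: list[str] = []
    width = len(str(config.n_species))

    def add_individuals(parent: dendropy.Node, sp: str, k: int, prefix: str, depth: float):
        for j in range(1, k + 1):
            leaf = dendropy.Node(taxon=tns2.new_taxon(f"{prefix}_i{j}"))
            parent.add_child(leaf)
            leaf.edge.length = depth / 2.0
            species_of[f"{prefix}_i{j}"] = sp

    for i, leaf in enumerate(species_leaves):
        sp = f"Species {i + 1:0{width}d}"
        prefix = f"s{i + 1:0{width}d}"
        k = counts[i]
        if k == 1:
            leaf.taxon = tns2.new_taxon(f"{prefix}_i1")
            species_of[f"{prefix}_i1"] = sp
            true_intra[sp] = 0.0
        elif i in deep_idx:
            deep_species.append(sp)
            stem = max(config.deep_split_height - config.intraspecific_height, 0.0) / 2.0
            k1 = max(1, k // 2)
            sizes = (k1, k - k1)
            offset = 0
            for c, size in enumerate(sizes):
                sub = dendropy.Node()
                leaf.add_child(sub)
                sub.edge.length = stem
                for j in range(offset + 1, offset + size + 1):
                    ind = dendropy.Node(taxon=tns2.new_taxon(f"{prefix}_i{j}"))
                    sub.add_child(ind)
                    ind.edge.length = config.intraspecific_height / 2.0
                    species_of[f"{prefix}_i{j}"] = sp
                offset += size
            n_pairs = k * (k - 1) / 2
            n_cross = sizes[0] * sizes[1]
            true_intra[sp] = (
                (n_pairs - n_cross) * config.intraspecific_height
                + n_cross * (2 * stem + config.intraspecific_height)
            ) / n_pairs
        else:
            add_individuals(leaf, sp, k, prefix, config.intraspecific_height)
            true_intra[sp] = config.intraspecific_height

    outgroup_id = None
    if config.outgroup:
        outgroup_id = "outgroup_i1"
        new_root = dendropy.Node()
        old_root = tree.seed_node
        tree.seed_node = new_root
        new_root.add_child(old_root)
        old_root.edge.length = 0.5 * config.interspecific_height
        og = dendropy.Node(taxon=tns2.new_taxon(outgroup_id))
        new_root.add_child(og)
        og.edge.length = 2.5 * config.interspecific_height
        species_of[outgroup_id] = "Outgroup taxon"
    tree.is_rooted = True

    truth = TruthTable(
        species_of=species_of,
        monophyletic={sp: True for sp in true_intra},
        true_intra_divergence=true_intra,
        deep_split_species=sorted(deep_species),
        contaminant_ids=[],
        outgroup_id=outgroup_id,
    )
    return tree, truth


def _hky_eigensystem(pi: np.ndarray, kappa: float):
    """Eigendecomposition of the normalized HKY rate matrix."""
    transition = np.zeros((4, 4), dtype=bool)
    for a, b in ((0, 2), (2, 0), (1, 3), (3, 1)):  # A<->G, C<->T
        transition[a, b] = True
    Q = np.where(transition, kappa, 1.0) * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))  # mean instantaneous rate
    Q /= mu
    sq = np.sqrt(pi)
    S = (Q * sq[:, None]) / sq[None, :]
    lam, V = np.linalg.eigh((S + S.T) / 2.0)
    left = V.T * sq[None, :]  # V^T diag(sqrt(pi))
    right = V / sq[:, None]  # diag(1/sqrt(pi)) V
    return lam, right, left


def _site_rates(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-site rate multipliers with mean 1 across all sites."""
    L = config.length
    rates = np.ones(L)
    invariant = rng.random(L) < config.p_inv
    rates[invariant] = 0.0
    n_var = int((~invariant).sum())
    if n_var:
        if config.gamma_alpha is not None:
            g = rng.gamma(config.gamma_alpha, 1.0 / config.gamma_alpha, size=n_var)
        else:
            g = np.ones(n_var)
        rates[~invariant] = g / (1.0 - config.p_inv)
    return rates


def _frame0_stop_codons(seq: np.ndarray) -> list[int]:
    """Indices of frame-0 codons that are vertebrate-mito stops."""
    text = "".join(BASES[b] for b in seq)
    return [
        c for c in range(len(text) // 3) if text[3 * c : 3 * c + 3] in MITO_STOPS
    ]


def evolve_sequences(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    truth: TruthTable | None = None,
) -> Alignment:
    """Evolve sequences down the tree under HKY(+I+G); no indels.

    With ``preserve_reading_frame`` on, the root sequence is drawn
    stop-free in frame 0 and any substitution creating an in-frame stop is
    rejected (the affected codon positions revert to the parent state), so
    clean simulated barcodes always pass the pseudogene screen.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    pi = config.pi()
    lam, right, left = _hky_eigensystem(pi, config.kappa)
    rates = _site_rates(config, rng)
    L = config.length

    root_seq = rng.choice(4, size=L, p=pi)
    if config.preserve_reading_frame:
        while True:
            bad = _frame0_stop_codons(root_seq)
            if not bad:
                break
            for c in bad:
                root_seq[3 * c : 3 * c + 3] = rng.choice(4, size=3, p=pi)

    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = seqs[id(node.parent_node)]
        t = node.edge.length or 0.0
        if t == 0.0:
            child = parent.copy()
        else:
            # per-site transition matrices via the spectral form
            E = np.exp(np.outer(lam, t * rates))  # (4, L)
            rowA = right[parent]  # (L, 4)
            probs = np.einsum("lk,kl,kj->lj", rowA, E, left)
            probs = np.clip(probs, 0.0, None)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(L)
            child = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.int64)
            child = np.minimum(child, 3)
            if config.preserve_reading_frame:
                for c in _frame0_stop_codons(child):
                    child[3 * c : 3 * c + 3] = parent[3 * c : 3 * c + 3]
        seqs[id(node)] = child

    records = []
    species_of = truth.species_of if truth else {}
    for leaf in sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label):
        label = leaf.taxon.label
        sp = species_of.get(label, "")
        records.append(
            SequenceRecord(
                id=label,
                seq="".join(BASES[b] for b in seqs[id(leaf)]),
                species=sp,
                outgroup=label == (truth.outgroup_id if truth else None),
            )
        )
    return Alignment(records)


def inject_numts(
    alignment: Alignment,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Alignment, list[str]]:
    """Turn a fraction of ingroup sequences into pseudogene mimics.

    Each contaminant receives one vertebrate-mito stop codon at a uniform
    in-frame codon position; returns the new alignment and contaminant ids.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if config.numt_rate == 0.0:
        return alignment, []
    candidates = [i for i, r in enumerate(alignment) if not r.outgroup]
    n_contam = int(round(config.numt_rate * len(candidates)))
    chosen = sorted(rng.choice(candidates, size=n_contam, replace=False).tolist())
    records = list(alignment.records)
    contaminants = []
    for i in chosen:
        rec = records[i]
        n_codons = len(rec.seq) // 3
        c = int(rng.integers(n_codons))
        stop = _STOP_LIST[int(rng.integers(len(_STOP_LIST)))]
        seq = rec.seq[: 3 * c] + stop + rec.seq[3 * c + 3 :]
        records[i] = replace(rec, seq=seq)
        contaminants.append(rec.id)
    return Alignment(records), contaminants


@dataclass
class SimulatedDataset:
    alignment: Alignment
    tree: dendropy.Tree
    truth: TruthTable
    config: SimulationConfig


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """End-to-end generation: genealogy, sequences, optional contaminants."""
    rng = np.random.default_rng(config.seed)
    tree, truth = simulate_species_tree(config, rng)
    alignment = evolve_sequences(tree, config, rng, truth=truth)
    alignment, contaminants = inject_numts(alignment, config, rng)
    truth.contaminant_ids = contaminants
    return SimulatedDataset(alignment=alignment, tree=tree, truth=truth, config=config)
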